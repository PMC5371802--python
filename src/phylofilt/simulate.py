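"""Mock-community generation for end-to-end pipeline testing.

The generators emulate a triplicate-PCR amplicon survey plus a small
metagenome fraction:

* a *true community* with lognormally distributed relative abundances and
  ranked synthetic lineages, some truncated above species level;
* per-replicate OTU counts drawn multinomially at a fixed sequencing
  depth, with PCR/sequencing artefacts appended as count-1 OTUs in exactly
  one replicate, and terrestrial contaminant lineages spiked in at
  configurable counts;
* a metagenome hit file (BLAST tabular) whose annotations follow a
  configurable superkingdom mixture and share a configurable fraction of
  genera with the amplicon community;
* FASTQ reads with i.i.d. per-base qualities for exercising the QC rules.

Every generator is bit-reproducible under its seed and records
``(spec, seed)`` in a provenance block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from io import StringIO

import numpy as np
import pandas as pd

from .io import write_blast_tabular
from .model import (
    BlastHit,
    Lineage,
    OtuTable,
    PhylotypeLabel,
    RANKS_ICTV,
    RANKS_SILVA,
    ValidationError,
)
from .annotate import TaxonomyMap
from .phylotypes import phylotype_label

__all__ = [
    "CommunitySpec",
    "NoiseSpec",
    "MetagenomeSpec",
    "Community",
    "GroundTruth",
    "sample_community",
    "simulate_otu_tables",
    "simulate_metagenome_hits",
    "simulate_fastq",
    "DEFAULT_CONTAMINANTS",
]

#: Terrestrial lineages spiked into amplicon tables by default, at count 1
#: each — crop/plant genera that have no business in a marine sample and
#: that per-replicate singleton removal is expected to eliminate.
DEFAULT_CONTAMINANTS: tuple[tuple[str, int], ...] = (
    ("Eukaryota;Streptophyta;Magnoliopsida;Fabales;Fabaceae;Cicer;Cicer arietinum", 1),
    ("Eukaryota;Streptophyta;Magnoliopsida;Lamiales;Pedaliaceae;Sesamum;Sesamum indicum", 1),
    ("Eukaryota;Streptophyta;Magnoliopsida;Solanales;Solanaceae;Nicotiana;Nicotiana sylvestris", 1),
)

#: Default truncation-depth distribution over lineage depths 1..7
#: (domain .. species): most taxa resolve to species, a tail stops higher.
DEFAULT_DEPTH_PROBS: tuple[float, ...] = (0.01, 0.02, 0.03, 0.04, 0.10, 0.20, 0.60)


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a true community.

    Relative abundances follow a lognormal species-abundance model with the
    given location/scale; ``depth_probs[d-1]`` is the probability a lineage
    is assigned down to depth ``d`` of the 7-rank order only.
    """

    n_taxa: int = 150
    lognormal_mean: float = 0.0
    lognormal_sigma: float = 1.5
    depth_probs: tuple[float, ...] = DEFAULT_DEPTH_PROBS
    domain: str = "Bacteria"
    label_prefix: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 0:
            raise ValidationError("n_taxa must be >= 0")
        if abs(sum(self.depth_probs) - 1.0) > 1e-9 or len(self.depth_probs) != len(RANKS_SILVA):
            raise ValidationError("depth_probs must have 7 entries summing to 1")


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate structure and artefact model for OTU-table simulation.

    ``spurious_otu_rate`` is the expected number of artefact OTUs per unit
    of true read mass (depth × replicates); each artefact appears with
    count exactly 1 in one replicate.  ``contaminants`` are (semicolon
    lineage, spike count) pairs, spiked into one replicate each.
    """

    n_replicates: int = 3
    depth: int = 10_000
    spurious_otu_rate: float = 5e-3
    contaminants: tuple[tuple[str, int], ...] = DEFAULT_CONTAMINANTS
    messy_artefacts: bool = False
    ensure_detectable: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("need at least one replicate")
        if self.depth < 0 or self.spurious_otu_rate < 0:
            raise ValidationError("depth and spurious_otu_rate must be >= 0")
        if self.depth == 0 and self.spurious_otu_rate > 0:
            raise ValidationError("spurious_otu_rate > 0 requires a nonzero depth")


@dataclass(frozen=True)
class MetagenomeSpec:
    """Composition of the simulated <0.45 µm metagenome annotation.

    The default superkingdom mixture matches contig-level annotation of a
    marine metagenome against a whole-organism protein database (heavily
    bacterial, with a sizeable unknown slice); ``overlap_fraction`` is the
    proportion of cellular-category genera drawn from the amplicon
    community rather than invented fresh.
    """

    n_queries: int = 2_000
    mixture: tuple[tuple[str, float], ...] = (
        ("Bacteria", 0.8685),
        ("unknown", 0.1103),
        ("Eukaryota", 0.0135),
        ("Viruses", 0.0075),
        ("Archaea", 0.0002),
    )
    overlap_fraction: float = 0.10
    max_hits_per_query: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.mixture)
        if abs(total - 1.0) > 1e-6:
            raise ValidationError("mixture weights must sum to 1")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValidationError("overlap_fraction must be in [0, 1]")


@dataclass
class Community:
    """A true community: one lineage and relative abundance per taxon."""

    lineages: list[Lineage]
    abundances: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.lineages)

    def phylotype_set(self) -> set[PhylotypeLabel]:
        return {phylotype_label(lin) for lin in self.lineages}

    def genera(self, domain: str | None = None) -> set[str]:
        out = set()
        for lin in self.lineages:
            if domain is not None and (lin.is_empty or lin.labels[0] != domain):
                continue
            g = lin.label_at("genus")
            if g:
                out.add(g)
        return out


@dataclass
class GroundTruth:
    """What the simulator actually put into an OTU table."""

    true_otu_ids: list[str]
    artefact_otu_ids: list[str]
    contaminant_otu_ids: list[str]
    true_phylotypes: set[PhylotypeLabel]
    contaminant_spikes: dict[str, int]  # otu id -> spiked count
    provenance: dict = field(default_factory=dict)


def _synthetic_lineage(
    rng: np.random.Generator,
    idx: int,
    spec: CommunitySpec,
) -> Lineage:
    """A ranked lineage over a shared synthetic namespace.

    Genus indices are drawn per taxon and mapped deterministically up the
    tree (several genera per family, several families per order, ...), so
    coarser ranks are shared between taxa as in a real taxonomy.
    """
    p = spec.label_prefix or spec.domain[:3].lower()
    n_genera = max(1, int(round(spec.n_taxa * 0.6)))
    g = int(rng.integers(0, n_genera))
    fam, order, cls, phyl = g // 4, g // 12, g // 36, g // 108
    labels = [
        spec.domain,
        f"{p}_phylum{phyl}",
        f"{p}_class{cls}",
        f"{p}_order{order}",
        f"{p}_family{fam}",
        f"{p}_genus{g}",
        f"{p}_genus{g} sp. {idx}",
    ]
    depth = int(rng.choice(np.arange(1, 8), p=spec.depth_probs))
    return Lineage.from_labels(labels[:depth])


def sample_community(spec: CommunitySpec) -> Community:
    """Draw a true community: lineages plus normalised lognormal abundances."""
    rng = np.random.default_rng(spec.seed)
    if spec.n_taxa == 0:
        return Community([], np.zeros(0), {"spec": asdict(spec), "seed": spec.seed})
    raw = rng.lognormal(spec.lognormal_mean, spec.lognormal_sigma, size=spec.n_taxa)
    abundances = raw / raw.sum()
    lineages = [_synthetic_lineage(rng, i, spec) for i in range(spec.n_taxa)]
    return Community(lineages, abundances, {"spec": asdict(spec), "seed": spec.seed})


def simulate_otu_tables(
    community: Community, noise: NoiseSpec
) -> tuple[OtuTable, GroundTruth]:
    """Draw per-replicate OTU counts with artefacts and contaminants.

    True counts are multinomial at ``noise.depth`` per replicate over the
    community's abundances.  Artefact OTUs are appended with count 1 in
    exactly one replicate (a geometric count >= 1 in "messy" mode) under a
    randomly truncated/perturbed copy of a true lineage.  Contaminants are
    spiked at their configured count into one replicate each.  With
    ``ensure_detectable`` (the default) every true taxon is guaranteed a
    count >= 2 in at least one replicate, so per-replicate singleton
    removal recovers the true community exactly.
    """
    rng = np.random.default_rng(noise.seed)
    reps = [f"rep{i + 1}" for i in range(noise.n_replicates)]
    n_true = len(community)

    rows: dict[str, list[int]] = {}
    taxonomy: dict[str, Lineage] = {}
    true_ids: list[str] = []

    if n_true:
        draws = np.stack(
            [rng.multinomial(noise.depth, community.abundances) for _ in reps], axis=1
        )
        if noise.ensure_detectable:
            # guarantee each true taxon a non-singleton presence somewhere
            for t in range(n_true):
                if draws[t].max() <= 1:
                    draws[t, int(rng.integers(0, noise.n_replicates))] = 2
        for t in range(n_true):
            oid = f"otu{t:05d}"
            rows[oid] = draws[t].tolist()
            taxonomy[oid] = community.lineages[t]
            true_ids.append(oid)

    artefact_ids: list[str] = []
    n_artefacts = (
        int(rng.poisson(noise.spurious_otu_rate * noise.depth * noise.n_replicates))
        if noise.spurious_otu_rate > 0 and n_true
        else 0
    )
    for a in range(n_artefacts):
        oid = f"art{a:05d}"
        src = community.lineages[int(rng.integers(0, n_true))]
        depth = int(rng.integers(0, len(src.ranks) + 1))
        lin = src.truncated(depth)
        if lin.ranks and rng.random() < 0.5:
            # perturb the tail label so the artefact founds a new phylotype
            rank, label = lin.ranks[-1]
            lin = Lineage(lin.ranks[:-1] + ((rank, f"{label}-art{a}"),))
        count = 1 if not noise.messy_artefacts else int(rng.geometric(0.6))
        vec = [0] * noise.n_replicates
        vec[int(rng.integers(0, noise.n_replicates))] = count
        rows[oid] = vec
        taxonomy[oid] = lin
        artefact_ids.append(oid)

    contaminant_ids: list[str] = []
    spikes: dict[str, int] = {}
    for c, (lin_text, spike) in enumerate(noise.contaminants):
        oid = f"contam{c:02d}"
        vec = [0] * noise.n_replicates
        vec[int(rng.integers(0, noise.n_replicates))] = int(spike)
        rows[oid] = vec
        taxonomy[oid] = Lineage.from_string(lin_text)
        contaminant_ids.append(oid)
        spikes[oid] = int(spike)

    counts = pd.DataFrame.from_dict(rows, orient="index", columns=reps)
    table = OtuTable(counts, taxonomy)
    truth = GroundTruth(
        true_otu_ids=true_ids,
        artefact_otu_ids=artefact_ids,
        contaminant_otu_ids=contaminant_ids,
        true_phylotypes=community.phylotype_set(),
        contaminant_spikes=spikes,
        provenance={"noise": asdict(noise), "seed": noise.seed},
    )
    return table, truth


#: Synthetic viral namespace used for the "Viruses" slice of the
#: metagenome: tailed phages plus the giant-virus families, with weights
#: shaped like a marine dsDNA virome.
_VIRAL_FAMILIES: tuple[tuple[str, str, float], ...] = (
    ("Caudovirales", "Myoviridae", 0.26),
    ("Caudovirales", "Siphoviridae", 0.22),
    ("Caudovirales", "Podoviridae", 0.10),
    ("Megavirales", "Phycodnaviridae", 0.13),
    ("Megavirales", "Mimiviridae", 0.08),
)


def _viral_lineage(rng: np.random.Generator, idx: int) -> Lineage:
    weights = np.array([w for _, _, w in _VIRAL_FAMILIES])
    weights = weights / weights.sum()
    order, family, _ = _VIRAL_FAMILIES[int(rng.choice(len(_VIRAL_FAMILIES), p=weights))]
    genus = f"{family[:-4]}virus{int(rng.integers(0, 10))}"
    labels = ["Viruses", order, family, f"{family}-sub", genus, f"{genus} sp. {idx}"]
    return Lineage.from_labels(labels, RANKS_ICTV)


def simulate_metagenome_hits(
    community: Community, spec: MetagenomeSpec
) -> tuple[str, TaxonomyMap, dict[str, str]]:
    """Emit a BLAST tabular hit file plus the taxonomy map resolving it.

    Each query gets 1..max_hits hits; the intended subject carries the top
    bit-score, so top-hit selection recovers the configured category
    mixture.  Queries in the "unknown" slice hit a subject deliberately
    absent from the emitted map.  Returns (tabular text, taxonomy map,
    query-id -> category ground truth).
    """
    rng = np.random.default_rng(spec.seed)
    categories = [c for c, _ in spec.mixture]
    weights = np.array([w for _, w in spec.mixture])
    community_genera = {
        dom: sorted(community.genera(dom)) for dom in ("Bacteria", "Eukaryota", "Archaea")
    }

    taxmap: dict[str, Lineage] = {}
    truth: dict[str, str] = {}
    hits: list[BlastHit] = []

    def _decoy_subject(i: int) -> str:
        sid = f"decoy{i:06d}"
        if sid not in taxmap:
            labels = ["Bacteria", "dec_phylum0", "dec_class0", "dec_order0",
                      "dec_family0", f"DecoyGenus{i % 97}"]
            taxmap[sid] = Lineage.from_labels(labels)
        return sid

    for q in range(spec.n_queries):
        qid = f"query{q:06d}"
        cat = categories[int(rng.choice(len(categories), p=weights))]
        truth[qid] = cat
        if cat == "unknown":
            sid = f"dark{q:06d}"  # deliberately absent from the taxonomy map
        elif cat == "Viruses":
            sid = f"vir{q:06d}"
            taxmap[sid] = _viral_lineage(rng, q)
        else:
            sid = f"cell{q:06d}"
            pool = community_genera.get(cat) or []
            if pool and rng.random() < spec.overlap_fraction:
                genus = pool[int(rng.integers(0, len(pool)))]
            else:
                genus = f"MetaGenus{cat[:3]}{q}"
            labels = [cat, f"m_phylum{q % 13}", f"m_class{q % 29}",
                      f"m_order{q % 47}", f"m_family{q % 71}", genus]
            taxmap[sid] = Lineage.from_labels(labels)

        n_hits = int(rng.integers(1, spec.max_hits_per_query + 1))
        top_bits = float(rng.uniform(120, 300))
        qlen = 100
        for h in range(n_hits):
            bit = top_bits if h == 0 else float(rng.uniform(40, top_bits - 1e-3))
            subject = sid if h == 0 else _decoy_subject(int(rng.integers(0, 500)))
            evalue = 10.0 ** -float(rng.uniform(6, 40))
            alen = int(rng.integers(50, qlen + 1))
            hits.append(
                BlastHit(
                    query_id=qid,
                    subject_id=subject,
                    pct_identity=float(rng.uniform(70, 100)),
                    align_length=alen,
                    mismatches=int(rng.integers(0, 10)),
                    gap_opens=int(rng.integers(0, 3)),
                    q_start=1,
                    q_end=alen,
                    s_start=1,
                    s_end=alen,
                    evalue=evalue,
                    bit_score=round(bit, 1),
                )
            )

    buf = StringIO()
    write_blast_tabular(hits, buf)
    return buf.getvalue(), TaxonomyMap(taxmap, source="synthetic"), truth


def simulate_fastq(n_reads: int, length: int, p_good_base: float, seed: int) -> str:
    """FASTQ text with i.i.d. per-base qualities.

    Each base is "good" (Q drawn uniformly in 20..40) with probability
    ``p_good_base``, else "bad" (Q in 2..19), so the fraction of reads
    surviving a Q20/95% filter follows a binomial tail exactly.
    """
    if not 0.0 <= p_good_base <= 1.0:
        raise ValidationError("p_good_base must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = StringIO()
    bases_alphabet = np.array(list("ACGT"))
    for i in range(n_reads):
        bases = "".join(rng.choice(bases_alphabet, size=length))
        good = rng.random(length) < p_good_base
        quals = np.where(
            good,
            rng.integers(20, 41, size=length),
            rng.integers(2, 20, size=length),
        )
        qstr = "".join(chr(int(q) + 33) for q in quals)
        out.write(f"@simread{i:06d}\n{bases}\n+\n{qstr}\n")
    return out.getvalue()
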