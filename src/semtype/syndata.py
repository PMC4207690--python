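"""Self-contained synthetic seminal-microbiome cohort generator.

Builds everything the downstream analysis needs without external data: a 16S
reference set (sequences, taxonomy, rooted branch-length tree), per-sample
paired-end amplicon reads with substitution errors and realistic Phred decay,
and clinical metadata whose abnormality rates are coupled to the planted
community type.

Three community types are planted, matching the study design the package
reimplements: a Pseudomonas-predominant type (G1, mean proportion 0.161), a
Lactobacillus-predominant type (G2, 0.323) and a Prevotella-predominant type
(G3, 0.263), with normal-semen probabilities 0.20, 0.527 and 0.125 and default
group sizes 25/55/16 in a 96-sample cohort. Sample-to-sample variation around
each type's genus means is Dirichlet with configurable precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .assoc import CASA_METRICS, CRITERIA, ClinicalRecord

__all__ = [
    "ReferenceRecord",
    "ReferenceDB",
    "CommunityTypeSpec",
    "SimulatedSample",
    "SimulatedCohort",
    "CohortConfig",
    "DEFAULT_TYPE_SPECS",
    "make_reference",
    "sample_composition",
    "simulate_reads",
    "simulate_clinical",
    "simulate_cohort",
    "simulate_case_control_profiles",
    "pairwise_identity",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = dict(zip("ACGT", "TGCA"))

# Fig-2-tier abundant genera followed by filler genera that absorb the
# remaining community mass; all appear in the source cohort's genus tables.
ABUNDANT_GENERA = (
    "Lactobacillus",
    "Pseudomonas",
    "Prevotella",
    "Gardnerella",
    "Rhodanobacter",
    "Streptococcus",
    "Finegoldia",
    "Haemophilus",
)
FILLER_GENERA = (
    "Enterobacter",
    "Dietzia",
    "Propionibacterium",
    "Atopobium",
    "Corynebacterium",
    "Veillonella",
)
DEFAULT_GENERA = ABUNDANT_GENERA + FILLER_GENERA

# Named species for the genera the classifier and associations care about.
_SPECIES_NAMES = {
    "Lactobacillus": ("Lactobacillus iners", "Lactobacillus crispatus"),
    "Prevotella": ("uncultured Prevotella sp.", "Prevotella bivia"),
    "Gardnerella": ("uncultured Gardnerella sp.", "Gardnerella vaginalis"),
    "Pseudomonas": ("uncultured Pseudomonas sp.", "Pseudomonas putida"),
    "Haemophilus": ("Haemophilus parainfluenzae", "uncultured Haemophilus sp."),
}


@dataclass(frozen=True)
class ReferenceRecord:
    seq_id: str
    sequence: str
    genus: str
    species: str


@dataclass
class ReferenceDB:
    """16S reference records plus a rooted branch-length phylogeny (newick)."""

    records: list[ReferenceRecord]
    newick: str

    def by_id(self) -> dict[str, ReferenceRecord]:
        return {r.seq_id: r for r in self.records}

    def taxonomy(self) -> dict[str, tuple[str, str]]:
        return {r.seq_id: (r.genus, r.species) for r in self.records}

    @property
    def species_ids(self) -> list[str]:
        return [r.seq_id for r in self.records]

    def tree(self):
        from skbio import TreeNode

        return TreeNode.read([self.newick], convert_underscores=False)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.seq_id} {r.species}\n{r.sequence}\n")

    def write_taxonomy(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("seq_id\tgenus\tspecies\n")
            for r in self.records:
                fh.write(f"{r.seq_id}\t{r.genus}\t{r.species}\n")

    def write_newick(self, path) -> None:
        Path(path).write_text(self.newick + "\n")

    @classmethod
    def read(cls, fasta_path, taxonomy_path, newick_path) -> "ReferenceDB":
        import pandas as pd
        from Bio import SeqIO

        tax = pd.read_csv(taxonomy_path, sep="\t").set_index("seq_id")
        records = []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            row = tax.loc[rec.id]
            records.append(
                ReferenceRecord(rec.id, str(rec.seq), row["genus"], row["species"])
            )
        return cls(records=records, newick=Path(newick_path).read_text().strip())


@dataclass
class CommunityTypeSpec:
    """Mean genus composition, Dirichlet precision, and clinical coupling."""

    name: str
    genus_means: dict[str, float]
    concentration: float = 25.0
    p_normal: float = 0.5

    def __post_init__(self) -> None:
        vals = np.array(list(self.genus_means.values()))
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("genus means must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"genus means must sum to 1, got {vals.sum()!r}")
        if not 0.0 <= self.p_normal <= 1.0:
            raise ValueError("p_normal must lie in [0, 1]")


def _type_means(anchor_genus: str, anchor: float, named: dict[str, float]) -> dict[str, float]:
    """Genus-mean map with the anchored maximum exact and the rest summing to 1-anchor.

    Any default genera not named share the leftover mass equally; the non-anchor
    entries are rescaled so the vector sums to exactly 1 with the anchor at its
    printed value.
    """
    means = {anchor_genus: anchor}
    means.update(named)
    rest = 1.0 - sum(means.values())
    fillers = [g for g in DEFAULT_GENERA if g not in means]
    for g in fillers:
        means[g] = rest / len(fillers)
    others = {g: means[g] for g in DEFAULT_GENERA if g != anchor_genus}
    scale = (1.0 - anchor) / sum(others.values())
    ordered = {
        g: (anchor if g == anchor_genus else others[g] * scale) for g in DEFAULT_GENERA
    }
    assert max(ordered.values()) == anchor
    assert abs(sum(ordered.values()) - 1.0) < 1e-12
    return ordered


def _default_type_specs() -> dict[str, CommunityTypeSpec]:
    # Each type carries, beyond its anchored predominant genus, the secondary
    # signature its co-occurrence subnetwork describes: Enterobacter,
    # Rhodanobacter and Corynebacterium with the Pseudomonas type;
    # Gardnerella, Atopobium and Propionibacterium with the Lactobacillus
    # type; Propionibacterium and Dietzia with the Prevotella type. Cohort
    # means under the 25/55/16 weighting stay close to the printed overall
    # genus means.
    g1 = _type_means(
        "Pseudomonas",
        0.161,
        {
            "Lactobacillus": 0.033,
            "Prevotella": 0.020,
            "Gardnerella": 0.005,
            "Haemophilus": 0.060,
            "Rhodanobacter": 0.140,
            "Streptococcus": 0.080,
            "Finegoldia": 0.100,
            "Enterobacter": 0.155,
            "Dietzia": 0.020,
            "Propionibacterium": 0.010,
            "Atopobium": 0.005,
            "Corynebacterium": 0.130,
            "Veillonella": 0.081,
        },
    )
    g2 = _type_means(
        "Lactobacillus",
        0.323,
        {
            "Pseudomonas": 0.075,
            "Prevotella": 0.050,
            "Gardnerella": 0.080,
            "Haemophilus": 0.015,
            "Rhodanobacter": 0.030,
            "Streptococcus": 0.090,
            "Finegoldia": 0.050,
            "Enterobacter": 0.020,
            "Dietzia": 0.020,
            "Propionibacterium": 0.060,
            "Atopobium": 0.080,
            "Corynebacterium": 0.047,
            "Veillonella": 0.060,
        },
    )
    g3 = _type_means(
        "Prevotella",
        0.263,
        {
            "Lactobacillus": 0.033,
            "Pseudomonas": 0.075,
            "Gardnerella": 0.005,
            "Haemophilus": 0.090,
            "Rhodanobacter": 0.020,
            "Streptococcus": 0.040,
            "Finegoldia": 0.090,
            "Enterobacter": 0.020,
            "Dietzia": 0.140,
            "Propionibacterium": 0.150,
            "Atopobium": 0.020,
            "Corynebacterium": 0.030,
            "Veillonella": 0.024,
        },
    )
    return {
        "G1": CommunityTypeSpec("G1", g1, concentration=25.0, p_normal=0.20),
        "G2": CommunityTypeSpec("G2", g2, concentration=25.0, p_normal=0.527),
        "G3": CommunityTypeSpec("G3", g3, concentration=25.0, p_normal=0.125),
    }


DEFAULT_TYPE_SPECS = _default_type_specs()

#: Default group sizes of the simulated 96-sample cohort.
DEFAULT_GROUP_SIZES = {"G1": 25, "G2": 55, "G3": 16}


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, n_sub: int) -> np.ndarray:
    """Substitute exactly n_sub distinct positions with a different base."""
    out = seq.copy()
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    for p in pos:
        choices = _BASES[_BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity between two sequences (edit-distance based)."""
    import edlib

    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def make_reference(
    n_genera: int = len(DEFAULT_GENERA),
    species_per_genus: int = 2,
    seq_len: int = 250,
    seed: int = 0,
    genus_names: Sequence[str] | None = None,
    max_identity: float = 0.97,
    max_attempts: int = 20,
) -> ReferenceDB:
    """Simulate a 16S reference set with a genus-clade phylogeny.

    Genus ancestors are independent random sequences (far below the identity
    ceiling); species diverge from their genus ancestor by ~2.5% substitutions
    each, so any two species — including congeners — stay below ``max_identity``
    pairwise identity while error-free reads map back at 100%. The invariant is
    verified exhaustively; generation is retried up to ``max_attempts`` times.
    """
    if n_genera < 2:
        raise ValueError("need at least 2 genera")
    if seq_len < 150:
        raise ValueError("reference sequences must be at least 150 nt")
    if genus_names is None:
        genus_names = list(DEFAULT_GENERA)[:n_genera]
        genus_names += [f"Genus{i:02d}" for i in range(len(genus_names), n_genera)]
    rng = np.random.default_rng(seed)
    n_species_sub = max(3, int(round(0.025 * seq_len)))  # ~2.5% divergence
    best_achieved = 0.0
    for _ in range(max_attempts):
        records: list[ReferenceRecord] = []
        genus_clades = []
        for gi, genus in enumerate(genus_names):
            ancestor = _random_seq(rng, seq_len)
            leaves = []
            for si in range(species_per_genus):
                seq = _mutate(rng, ancestor, n_species_sub)
                seq_id = f"ref_{gi:02d}_{si}"
                species = _species_name(genus, si)
                records.append(
                    ReferenceRecord(seq_id, seq.tobytes().decode(), genus, species)
                )
                leaves.append(f"{seq_id}:{n_species_sub / seq_len:.6f}")
            if len(leaves) == 1:
                genus_clades.append(f"{leaves[0].split(':')[0]}:0.35")
            else:
                genus_clades.append("(" + ",".join(leaves) + "):0.35")
        newick = "(" + ",".join(genus_clades) + ");"
        worst = 0.0
        ok = True
        for i in range(len(records)):
            for j in range(i + 1, len(records)):
                ident = pairwise_identity(records[i].sequence, records[j].sequence)
                worst = max(worst, ident)
                if ident >= max_identity:
                    ok = False
        best_achieved = max(best_achieved, 0.0) if ok else max(best_achieved, worst)
        if ok:
            return ReferenceDB(records=records, newick=newick)
    raise RuntimeError(
        f"could not build a reference with all pairwise identities < {max_identity}; "
        f"worst achieved {best_achieved:.4f}"
    )


def _species_name(genus: str, index: int) -> str:
    named = _SPECIES_NAMES.get(genus, ())
    if index < len(named):
        return named[index]
    return f"uncultured {genus} sp. {index + 1}"


def _species_split(n: int) -> np.ndarray:
    """Fixed within-genus species weights: proportional to 1/(rank+1)."""
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def sample_composition(
    spec: CommunityTypeSpec,
    refdb: ReferenceDB,
    seed_or_rng,
) -> "np.ndarray":
    """Draw one species-level composition for a sample of the given type.

    Genus proportions are Dirichlet with mean ``spec.genus_means`` and
    precision ``spec.concentration``; each genus's mass is divided among its
    species by a fixed within-genus split. Genera in the spec but absent from
    the reference raise an error. Returns proportions over
    ``refdb.species_ids`` summing to 1.
    """
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) \
        else seed_or_rng
    genera = list(spec.genus_means)
    ref_genera = {r.genus for r in refdb.records}
    missing = [g for g in genera if g not in ref_genera]
    if missing:
        raise ValueError(f"genera not in reference: {missing}")
    means = np.array([spec.genus_means[g] for g in genera])
    if np.isinf(spec.concentration):
        genus_prop = means
    else:
        alpha = np.clip(means * spec.concentration, 1e-9, None)
        genus_prop = rng.dirichlet(alpha)
    comp = np.zeros(len(refdb.records))
    for g, gp in zip(genera, genus_prop):
        idx = [i for i, r in enumerate(refdb.records) if r.genus == g]
        comp[idx] = gp * _species_split(len(idx))
    total = comp.sum()
    if total > 0:
        comp = comp / total
    assert comp.min() >= 0 and abs(comp.sum() - 1.0) < 1e-9
    return comp


_PHRED_GOOD = chr(38 + 33)  # Q38
_PHRED_BAD = chr(15 + 33)  # Q15
_HAZARD_EARLY = 1e-4  # per-base chance of entering the low-quality state
_HAZARD_LATE = 0.02  # elevated hazard near the 3' end
_LATE_START = 110  # position where the elevated hazard begins


def _quality_string(rng: np.random.Generator, length: int) -> str:
    """Two-state (good Q38 / absorbing bad Q15) quality model, 3'-enriched."""
    hazard = np.full(length, _HAZARD_EARLY)
    if length > _LATE_START:
        hazard[_LATE_START:] = _HAZARD_LATE
    bad = rng.random(length) < hazard
    first = int(np.argmax(bad)) if bad.any() else length
    return _PHRED_GOOD * first + _PHRED_BAD * (length - first)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def simulate_reads(
    composition: np.ndarray,
    refdb: ReferenceDB,
    n_pairs: int,
    error_rate: float = 0.005,
    read_len: int = 150,
    seed_or_rng=0,
    barcode: str = "",
    sample_id: str = "S",
) -> list[tuple[tuple[str, str, str], tuple[str, str, str]]]:
    """Simulate paired-end amplicon reads from a species composition.

    Each pair picks a species proportional to ``composition``; the forward
    read covers the 5' end of the reference and the reverse read is the
    reverse complement of its 3' end. Substitution errors are i.i.d. per base
    at ``error_rate``; qualities follow a two-state Phred model tuned so that
    >95% of error-free-length pairs survive the default QC. The barcode (with
    maximal quality) is prepended to the forward read.
    """
    if not 0.0 <= error_rate <= 0.01:
        raise ValueError("error_rate must lie in [0, 0.01]")
    ref_len = len(refdb.records[0].sequence)
    if read_len > ref_len:
        raise ValueError("read_len exceeds reference length")
    if n_pairs == 0:
        warnings.warn("n_pairs = 0: returning no reads")
        return []
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) \
        else seed_or_rng
    comp = np.asarray(composition, dtype=float)
    species_idx = rng.choice(len(refdb.records), size=n_pairs, p=comp / comp.sum())
    pairs = []
    for i, si in enumerate(species_idx):
        ref = refdb.records[si].sequence
        fwd = _add_errors(rng, ref[:read_len], error_rate)
        rev = _add_errors(rng, _revcomp(ref[-read_len:]), error_rate)
        rid = f"{sample_id}_p{i:06d}"
        q1 = _quality_string(rng, read_len)
        q2 = _quality_string(rng, read_len)
        r1 = (rid + "/1", barcode + fwd, _PHRED_GOOD * len(barcode) + q1)
        r2 = (rid + "/2", rev, q2)
        pairs.append((r1, r2))
    return pairs


def _add_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for p in hit:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()


# Clinical value ranges. Normal draws sit strictly inside the normal band;
# abnormal draws sit beyond the threshold for that criterion.
_NORMAL_RANGES = {
    "volume": (1.5, 6.0),
    "concentration": (15e6, 120e6),
    "motility": (40.0, 75.0),
    "kruger": (5.5, 14.0),
    "iga": (0.0, 28.0),
    "atypical": (0.0, 0.9),
    "leukocytes": (0.0, 0.9e6),
}
_ABNORMAL_RANGES = {
    "volume": [(6.4, 9.0), (0.2, 1.2)],
    "concentration": [(1e6, 14.9e6)],
    "motility": [(5.0, 39.9)],
    "kruger": [(0.5, 5.0)],
    "iga": [(31.0, 80.0)],
    "atypical": [(1.0, 5.0)],
    "leukocytes": [(1e6, 5e6)],
}
# CASA metric (mean, sd) for draws; head elongation is handled separately.
_CASA_PARAMS = {
    "VAP": (50.0, 10.0),
    "VSL": (40.0, 9.0),
    "VCL": (80.0, 15.0),
    "ALH": (4.0, 1.0),
    "BCF": (25.0, 5.0),
    "STR": (80.0, 8.0),
    "LIN": (50.0, 10.0),
    "area": (10.0, 1.5),
}
# Planted monotone link: samples poor in Lactobacillus get rounder sperm heads.
_ELONGATION_BASE = 1.45
_ELONGATION_SLOPE = 0.6
_ELONGATION_SD = 0.08


def simulate_clinical(
    ctype: str,
    seed_or_rng=0,
    specs: Mapping[str, CommunityTypeSpec] | None = None,
    lactobacillus_proportion: float | None = None,
) -> ClinicalRecord:
    """Draw one clinical record for a sample of the given community type.

    With probability ``p_normal`` of the type, all seven criteria are normal;
    otherwise at least two criteria (2 + Poisson(0.8), capped at 7) are drawn
    abnormal, so the sample is a case under the default class rule. Raw values
    are uniform within the flag-consistent range. CASA head elongation carries
    the planted Lactobacillus link.
    """
    specs = DEFAULT_TYPE_SPECS if specs is None else specs
    spec = specs[ctype]
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) \
        else seed_or_rng
    if lactobacillus_proportion is None:
        lactobacillus_proportion = spec.genus_means.get("Lactobacillus", 0.0)
    normal = rng.random() < spec.p_normal
    abnormal_set: set[str] = set()
    if not normal:
        n_abn = min(7, 2 + rng.poisson(0.8))
        abnormal_set = set(rng.choice(list(CRITERIA), size=n_abn, replace=False))
    values = {}
    for crit in CRITERIA:
        if crit in abnormal_set:
            lo, hi = _ABNORMAL_RANGES[crit][rng.integers(len(_ABNORMAL_RANGES[crit]))]
        else:
            lo, hi = _NORMAL_RANGES[crit]
        values[crit] = float(rng.uniform(lo, hi))
    casa = {m: float(rng.normal(mu, sd)) for m, (mu, sd) in _CASA_PARAMS.items()}
    casa["head_elongation"] = float(
        _ELONGATION_BASE
        + _ELONGATION_SLOPE * lactobacillus_proportion
        + rng.normal(0.0, _ELONGATION_SD)
    )
    return ClinicalRecord(**values, casa=casa)


@dataclass
class SimulatedSample:
    sample_id: str
    ctype: str
    composition: np.ndarray  # over refdb.species_ids
    barcode: str
    pairs: list
    clinical: ClinicalRecord


@dataclass
class SimulatedCohort:
    refdb: ReferenceDB
    samples: list[SimulatedSample]

    def barcode_map(self) -> dict[str, str]:
        return {s.sample_id: s.barcode for s in self.samples}

    def true_labels(self):
        import pandas as pd

        return pd.Series({s.sample_id: s.ctype for s in self.samples})

    def clinical_records(self) -> dict[str, ClinicalRecord]:
        return {s.sample_id: s.clinical for s in self.samples}

    def write(self, outdir) -> None:
        """Write all cohort artifacts as plain-text files."""
        import pandas as pd

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.refdb.write_fasta(out / "reference.fasta")
        self.refdb.write_taxonomy(out / "taxonomy.tsv")
        self.refdb.write_newick(out / "reference.nwk")
        with open(out / "barcodes.tsv", "w") as fh:
            fh.write("sample_id\tbarcode\n")
            for s in self.samples:
                fh.write(f"{s.sample_id}\t{s.barcode}\n")
        with open(out / "reads_R1.fastq", "w") as f1, open(out / "reads_R2.fastq", "w") as f2:
            for s in self.samples:
                for (id1, s1, q1), (id2, s2, q2) in s.pairs:
                    f1.write(f"@{id1}\n{s1}\n+\n{q1}\n")
                    f2.write(f"@{id2}\n{s2}\n+\n{q2}\n")
        from .assoc import write_clinical_table

        write_clinical_table(self.clinical_records(), out / "clinical.tsv")
        truth = pd.DataFrame(
            [
                {"sample_id": s.sample_id, "ctype": s.ctype}
                | dict(zip(self.refdb.species_ids, s.composition))
                for s in self.samples
            ]
        )
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)


@dataclass
class CohortConfig:
    """All tunables of the synthetic cohort; defaults are the study conditions."""

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_pairs_per_sample: int = 5000
    error_rate: float = 0.005
    read_len: int = 150
    seq_len: int = 250
    n_genera: int = len(DEFAULT_GENERA)
    species_per_genus: int = 2
    concentration: float = 25.0
    barcode_len: int = 8

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))


def _make_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    out = []
    while len(out) < n:
        bc = _random_seq(rng, length).tobytes().decode()
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> SimulatedCohort:
    """Generate the full synthetic cohort from a single master seed.

    The master seed is fanned out through ``numpy.random.SeedSequence`` so the
    reference, each sample's composition, reads, and clinical record are all
    individually reproducible and the whole cohort is byte-identical per seed.
    """
    cfg = config or CohortConfig()
    ss = np.random.SeedSequence(seed)
    ref_seed, bc_seed, sample_root = ss.spawn(3)
    refdb = make_reference(
        n_genera=cfg.n_genera,
        species_per_genus=cfg.species_per_genus,
        seq_len=cfg.seq_len,
        seed=ref_seed,
    )
    specs = {
        name: CommunityTypeSpec(
            name, spec.genus_means, concentration=cfg.concentration, p_normal=spec.p_normal
        )
        for name, spec in DEFAULT_TYPE_SPECS.items()
    }
    n_total = sum(cfg.group_sizes.values())
    barcodes = _make_barcodes(np.random.default_rng(bc_seed), n_total, cfg.barcode_len)
    lacto_idx = [i for i, r in enumerate(refdb.records) if r.genus == "Lactobacillus"]
    samples = []
    sample_seeds = sample_root.spawn(n_total)
    i = 0
    for ctype in sorted(cfg.group_sizes):
        for _ in range(cfg.group_sizes[ctype]):
            sid = f"S{i + 1:03d}"
            rng = np.random.default_rng(sample_seeds[i])
            comp = sample_composition(specs[ctype], refdb, rng)
            pairs = simulate_reads(
                comp,
                refdb,
                cfg.n_pairs_per_sample,
                error_rate=cfg.error_rate,
                read_len=cfg.read_len,
                seed_or_rng=rng,
                barcode=barcodes[i],
                sample_id=sid,
            )
            clinical = simulate_clinical(
                ctype,
                seed_or_rng=rng,
                specs=specs,
                lactobacillus_proportion=float(comp[lacto_idx].sum()),
            )
            samples.append(
                SimulatedSample(sid, ctype, comp, barcodes[i], pairs, clinical)
            )
            i += 1
    return SimulatedCohort(refdb=refdb, samples=samples)


def simulate_case_control_profiles(
    n_case: int = 33,
    n_normal: int = 36,
    enriched_genus: str = "Prevotella",
    fold: float = 2.0,
    concentration: float = 25.0,
    seed: int = 0,
):
    """Genus-proportion profiles with one genus's mean multiplied in cases.

    Controls draw from the G2 genus means; cases draw from the same means with
    ``enriched_genus`` scaled by ``fold`` and the vector renormalized. Used for
    power and null calibration of the differential-abundance pipeline (pass
    ``fold=1`` for a null cohort).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    base = np.array(list(DEFAULT_TYPE_SPECS["G2"].genus_means.values()))
    genera = list(DEFAULT_TYPE_SPECS["G2"].genus_means)
    gi = genera.index(enriched_genus)
    target = fold * base[gi]
    if not 0.0 < target < 1.0:
        raise ValueError("fold takes the planted mean outside (0, 1)")
    # solve for the pre-normalization mass so the mean is exactly fold * base
    case_means = base.copy()
    others = base.sum() - base[gi]
    case_means[gi] = target * others / (1.0 - target)
    case_means /= case_means.sum()
    assert abs(case_means[gi] - target) < 1e-12
    rows, labels = [], []
    for i in range(n_normal):
        rows.append(rng.dirichlet(np.clip(base * concentration, 1e-9, None)))
        labels.append("normal")
    for i in range(n_case):
        rows.append(rng.dirichlet(np.clip(case_means * concentration, 1e-9, None)))
        labels.append("case")
    idx = [f"P{i + 1:03d}" for i in range(len(rows))]
    profile = pd.DataFrame(rows, index=idx, columns=genera)
    return profile, pd.Series(labels, index=idx, name="class")
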