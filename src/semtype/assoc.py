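"""Clinical flagging, case/normal classes, differential abundance, and co-occurrence.

Implements the statistical layer of the seminal-microbiome analysis: the seven
semen-quality criteria with their clinical thresholds, the normal/case class
rule, Mann-Whitney differential-abundance testing with an abundance pre-filter
and adaptive (two-stage) Benjamini-Hochberg FDR control, Fisher's exact test
with odds ratios for group enrichment, and Spearman co-occurrence networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClinicalRecord",
    "CriterionFlags",
    "CRITERIA",
    "CASA_METRICS",
    "flag_clinical",
    "define_classes",
    "mann_whitney",
    "abundance_filter",
    "adaptive_bh",
    "benjamini_hochberg",
    "tier",
    "fisher_or",
    "spearman_network",
    "ego_network",
    "differential_abundance",
    "casa_association",
    "read_clinical_table",
    "write_clinical_table",
]

#: The seven semen-quality criteria, in fixed reporting order.
CRITERIA = (
    "volume",
    "concentration",
    "motility",
    "kruger",
    "iga",
    "atypical",
    "leukocytes",
)

#: Computer-assisted semen analysis (CASA) metrics carried per sample.
CASA_METRICS = (
    "VAP",
    "VSL",
    "VCL",
    "ALH",
    "BCF",
    "STR",
    "LIN",
    "head_elongation",
    "area",
)


@dataclass
class ClinicalRecord:
    """One participant's semen-quality measurements.

    Units: volume in ml, concentration in cells/ml, motility / kruger / iga /
    atypical in percent, leukocytes in cells/ml; CASA velocities in um/s, ALH
    in um, BCF in Hz, STR/LIN in percent, area in um^2, head elongation
    dimensionless (length/width ratio).
    """

    volume: float
    concentration: float
    motility: float
    kruger: float
    iga: float
    atypical: float
    leukocytes: float
    casa: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("motility", "kruger", "iga", "atypical"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")
        if self.volume < 0:
            raise ValueError(f"volume must be >= 0, got {self.volume}")
        if self.concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")


@dataclass
class CriterionFlags:
    """Normal/abnormal flag per criterion; ``n_abnormal`` counts abnormal ones."""

    flags: dict[str, bool]  # criterion -> True if abnormal

    @property
    def n_abnormal(self) -> int:
        return sum(self.flags.values())

    def __getitem__(self, criterion: str) -> bool:
        return self.flags[criterion]


# Clinical reference thresholds. A sample is abnormal on a criterion when the
# stated condition holds; leukocyte counts below 1e6 cells/ml count as
# unobserved (normal) per WHO guidance.
LEUKOCYTE_OBSERVED = 1e6


def flag_clinical(rec: ClinicalRecord) -> CriterionFlags:
    """Apply the clinical reference thresholds to one record.

    Abnormal when: volume >= 6.4 or <= 1.2 ml; concentration < 15e6 cells/ml;
    motility < 40%; Kruger strict morphology <= 5%; antisperm IgA > 30%;
    atypical (very small sperm heads) >= 1%; leukocytes observed
    (>= 1e6 cells/ml).
    """
    missing = [c for c in CRITERIA if getattr(rec, c, None) is None]
    if missing:
        raise ValueError(f"clinical record missing fields: {missing}")
    flags = {
        "volume": rec.volume >= 6.4 or rec.volume <= 1.2,
        "concentration": rec.concentration < 15e6,
        "motility": rec.motility < 40.0,
        "kruger": rec.kruger <= 5.0,
        "iga": rec.iga > 30.0,
        "atypical": rec.atypical >= 1.0,
        "leukocytes": rec.leukocytes >= LEUKOCYTE_OBSERVED,
    }
    return CriterionFlags(flags=flags)


def define_classes(
    flags: Mapping[str, CriterionFlags], min_abnormal_case: int = 2
) -> pd.Series:
    """Assign each sample to ``normal`` / ``case`` / ``excluded``.

    A sample with zero abnormal criteria is ``normal``; one with at least
    ``min_abnormal_case`` abnormal criteria is a ``case``; anything in between
    is ``excluded`` from supervised comparisons.
    """
    out = {}
    for sample, f in flags.items():
        n = f.n_abnormal
        if n == 0:
            out[sample] = "normal"
        elif n >= min_abnormal_case:
            out[sample] = "case"
        else:
            out[sample] = "excluded"
    return pd.Series(out, name="class")


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Uses the exact null distribution when the pooled sample size is at most 20
    and there are no ties; otherwise the tie-corrected normal approximation
    with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires two nonempty samples")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p = 1")
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def abundance_filter(
    profile: pd.DataFrame, min_proportion: float = 0.0025
) -> list[str]:
    """Taxa whose cohort-mean proportion strictly exceeds ``min_proportion``.

    ``profile`` is a samples x taxa proportion matrix. The default 0.25%
    threshold is the pre-filter applied before multiple testing.
    """
    means = profile.mean(axis=0)
    return [t for t in profile.columns if means[t] > min_proportion]


def benjamini_hochberg(pvalues: Sequence[float], alpha: float = 0.05):
    """Plain Benjamini-Hochberg linear step-up. Returns (reject, adjusted)."""
    p = _check_pvalues(pvalues)
    reject, adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, adj


def adaptive_bh(pvalues: Sequence[float], alpha: float = 0.05):
    """Two-stage adaptive Benjamini-Hochberg procedure.

    Stage 1 runs BH at level alpha/(1+alpha); with r1 rejections the number of
    true nulls is estimated as m0 = m - r1 (m0 = m when r1 = 0); stage 2 runs
    BH at level alpha * m / m0.

    Returns
    -------
    reject : boolean array
    adjusted : array of adjusted p-values
    m0 : estimated number of true null hypotheses
    """
    p = _check_pvalues(pvalues)
    m = p.size
    alpha1 = alpha / (1.0 + alpha)
    r1 = int(multipletests(p, alpha=alpha1, method="fdr_bh")[0].sum())
    m0 = m - r1 if r1 > 0 else m
    if m0 == 0:  # stage 1 rejected every hypothesis
        return np.ones(m, dtype=bool), np.zeros(m), 0
    reject, bh_adj, _, _ = multipletests(p, alpha=alpha * m / m0, method="fdr_bh")
    adj = np.minimum(bh_adj * m0 / m, 1.0)
    return reject, adj, m0


def _check_pvalues(pvalues: Sequence[float]) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


#: Significance tiers used in the association tables; ``ns`` = not significant.
TIERS = (0.001, 0.01, 0.05)


def tier(p: float) -> str:
    """Finest significance threshold strictly above ``p`` (else ``'ns'``)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    for t in TIERS:
        if p < t:
            return str(t)
    return "ns"


def fisher_or(table: Sequence[Sequence[float]]):
    """Fisher's exact test (two-sided) and odds ratio for a 2x2 count table.

    The two-sided p-value sums hypergeometric probabilities of all tables with
    the observed margins that are no more probable than the observed table.
    The odds ratio is (a*d)/(b*c) with a 0.5 Haldane-Anscombe correction
    applied to every cell iff any cell is zero. A zero margin yields p = 1 and
    an undefined (NaN) odds ratio.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("fisher_or requires a 2x2 table of nonnegative integers")
    (a, b), (c, d) = t
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("zero margin in 2x2 table: p = 1, odds ratio undefined")
        return 1.0, float("nan")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orx = (a * d) / (b * c)
    return float(p), float(orx)


def spearman_network(
    genus_profile: pd.DataFrame, threshold: float = 0.4
) -> nx.Graph:
    """Genus co-occurrence network from pairwise Spearman correlation.

    An edge joins two genera when the absolute Spearman correlation (average
    ranks on ties) strictly exceeds ``threshold``. Constant-valued genera are
    excluded with a warning. Requires at least 3 samples.
    """
    if genus_profile.shape[0] < 3:
        raise ValueError("spearman_network requires at least 3 samples")
    keep = []
    for g in genus_profile.columns:
        if genus_profile[g].nunique() <= 1:
            warnings.warn(f"genus {g!r} has constant abundance; excluded from network")
        else:
            keep.append(g)
    net = nx.Graph(threshold=threshold)
    net.add_nodes_from(keep)
    sub = genus_profile[keep]
    if len(keep) >= 2:
        rho = sub.corr(method="spearman").to_numpy()
        for i, gi in enumerate(keep):
            for j in range(i + 1, len(keep)):
                if abs(rho[i, j]) > threshold:
                    net.add_edge(gi, keep[j], rho=float(rho[i, j]))
    return net


def ego_network(net: nx.Graph, center_genus: str, depth: int = 2) -> nx.Graph:
    """Subnetwork induced by nodes within graph distance ``depth`` of a genus."""
    if center_genus not in net:
        raise KeyError(f"genus {center_genus!r} not in network")
    return nx.ego_graph(net, center_genus, radius=depth)


def differential_abundance(
    profile: pd.DataFrame,
    classes: pd.Series,
    rank: str = "genus",
    comparison: str = "case-vs-normal",
    min_proportion: float = 0.0025,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-taxon Mann-Whitney tests with the abundance filter and adaptive FDR.

    ``classes`` must take exactly two values on the samples used (e.g. ``case``
    vs ``normal``; ``excluded`` samples are dropped). Significance tiers
    (0.05 / 0.01 / 0.001 on the raw p) are reported only for taxa passing the
    adaptive-BH screen at ``alpha``; the rest are ``ns``.
    """
    classes = classes[classes != "excluded"]
    groups = sorted(classes.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two classes, got {groups}")
    prof = profile.loc[classes.index]
    taxa = abundance_filter(prof, min_proportion)
    if not taxa:
        return pd.DataFrame(
            columns=["taxon", "rank", "comparison", "direction", "p", "q", "tier"]
        )
    g0 = prof.loc[classes == groups[0]]
    g1 = prof.loc[classes == groups[1]]
    rows = []
    for t in taxa:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = mann_whitney(g0[t], g1[t])
        direction = (
            f"enriched in {groups[0]}"
            if g0[t].mean() >= g1[t].mean()
            else f"enriched in {groups[1]}"
        )
        rows.append((t, rank, comparison, direction, p))
    out = pd.DataFrame(rows, columns=["taxon", "rank", "comparison", "direction", "p"])
    reject, adj, _ = adaptive_bh(out["p"].to_numpy(), alpha=alpha)
    out["q"] = adj
    out["significant"] = reject
    out["tier"] = [tier(p) if rej else "ns" for p, rej in zip(out["p"], reject)]
    return out


def casa_association(
    profile: pd.DataFrame,
    casa_table: pd.DataFrame,
    min_proportion: float = 0.0025,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of each (taxon, CASA metric) pair with adaptive FDR.

    Constant metrics are skipped with a warning. The abundance pre-filter is
    the same one used for the case/normal tests.
    """
    common = profile.index.intersection(casa_table.index)
    prof = profile.loc[common]
    casa = casa_table.loc[common]
    taxa = abundance_filter(prof, min_proportion)
    rows = []
    for metric in casa.columns:
        vals = casa[metric].to_numpy(dtype=float)
        if np.unique(vals).size <= 1:
            warnings.warn(f"CASA metric {metric!r} has zero variance; skipped")
            continue
        for t in taxa:
            rho, p = stats.spearmanr(prof[t].to_numpy(), vals)
            rows.append((t, metric, float(rho), float(p)))
    out = pd.DataFrame(rows, columns=["taxon", "metric", "rho", "p"])
    if len(out):
        reject, adj, _ = adaptive_bh(out["p"].to_numpy(), alpha=alpha)
        out["q"] = adj
        out["significant"] = reject
    else:
        out["q"] = []
        out["significant"] = []
    return out


def read_clinical_table(path) -> dict[str, ClinicalRecord]:
    """Read a clinical metadata TSV (sample_id, the 7 criteria, CASA columns)."""
    df = pd.read_csv(path, sep="\t", comment="#").set_index("sample_id")
    records = {}
    for sid, row in df.iterrows():
        casa = {m: float(row[m]) for m in CASA_METRICS if m in row}
        records[str(sid)] = ClinicalRecord(
            **{c: float(row[c]) for c in CRITERIA}, casa=casa
        )
    return records


def write_clinical_table(records: Mapping[str, ClinicalRecord], path) -> None:
    rows = []
    for sid, rec in records.items():
        row = {"sample_id": sid}
        row.update({c: getattr(rec, c) for c in CRITERIA})
        row.update({m: rec.casa.get(m, float("nan")) for m in CASA_METRICS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
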