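"""Read-pair taxonomic assignment and proportion profiles.

A read maps to a reference 16S sequence when its alignment identity is at
least 97% and both mates of the pair hit the same reference. Candidate
references come from exact k-mer seeding (default k = 15); each candidate is
then scored by a banded glocal alignment (the read aligned end-to-end against
the best-matching window of the reference, via edlib), with identity computed
as matching positions over the aligned read length. Counts are aggregated to
genus and species profiles; all downstream analysis uses proportions over
assigned reads, not raw counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .syndata import ReferenceDB

__all__ = [
    "Assignment",
    "TaxonProfile",
    "ReferenceIndex",
    "align_read",
    "assign_pair",
    "assign_sample",
    "build_profiles",
    "group_minor_taxa",
    "profile_cohort",
]

MIN_IDENTITY = 0.97


@dataclass(frozen=True)
class Assignment:
    """Outcome for one read pair: a reference hit or a reason it has none."""

    pair_id: str
    seq_id: str | None
    identity: float | None
    reason: str | None = None  # low_identity | discordant_mates | no_hit

    def __post_init__(self) -> None:
        if self.seq_id is not None and (
            self.identity is None or self.identity < MIN_IDENTITY
        ):
            raise ValueError("assigned reads must have identity >= 0.97")


class ReferenceIndex:
    """Exact k-mer index over reference sequences for candidate seeding."""

    def __init__(self, refdb: ReferenceDB, k: int = 15):
        if not refdb.records:
            raise ValueError("empty reference database")
        self.refdb = refdb
        self.k = k
        self.sequences = {r.seq_id: r.sequence for r in refdb.records}
        self._kmers: dict[str, set[str]] = {}
        for r in refdb.records:
            seq = r.sequence
            for i in range(len(seq) - k + 1):
                self._kmers.setdefault(seq[i : i + k], set()).add(r.seq_id)

    def candidates(self, read: str) -> set[str]:
        """References sharing at least one k-mer with the read (stride k)."""
        out: set[str] = set()
        for i in range(0, max(1, len(read) - self.k + 1), self.k):
            out |= self._kmers.get(read[i : i + self.k], set())
        return out


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def align_read(
    read: str,
    index: ReferenceIndex,
    min_identity: float = MIN_IDENTITY,
) -> list[tuple[str, float]]:
    """Hits (seq_id, identity) for one read, either orientation.

    Candidates are seeded by exact k-mers of the read and of its reverse
    complement; each candidate reference is aligned glocally (read end-to-end
    against its best reference window, band limited to the allowed error
    budget) and identity = 1 - edit_distance / read_length. Hits below
    ``min_identity`` are dropped; the best orientation per reference is kept.
    """
    if not set(read) <= set("ACGT"):
        raise ValueError("align_read requires an ACGT-only read")
    max_dist = int(np.floor((1.0 - min_identity) * len(read)))
    hits: dict[str, float] = {}
    for oriented in (read, _revcomp(read)):
        for seq_id in index.candidates(oriented):
            res = edlib.align(
                oriented, index.sequences[seq_id], mode="HW", task="distance", k=max_dist
            )
            d = res["editDistance"]
            if d < 0:  # beyond the band
                continue
            ident = 1.0 - d / len(read)
            if ident >= min_identity and ident > hits.get(seq_id, -1.0):
                hits[seq_id] = ident
    return sorted(hits.items())


def assign_pair(
    pair_id: str,
    hits_r1: Sequence[tuple[str, float]],
    hits_r2: Sequence[tuple[str, float]],
) -> Assignment:
    """Resolve a pair to the single best reference both mates agree on.

    Shared references are scored by mean mate identity; ties break by higher
    minimum mate identity, then lexicographically smaller seq_id. No shared
    reference means the mates are discordant; two empty hit lists mean no hit.
    """
    h1, h2 = dict(hits_r1), dict(hits_r2)
    if not h1 and not h2:
        return Assignment(pair_id, None, None, reason="no_hit")
    common = sorted(set(h1) & set(h2))
    if not common:
        return Assignment(pair_id, None, None, reason="discordant_mates")
    best = min(
        common,
        key=lambda s: (-(h1[s] + h2[s]) / 2.0, -min(h1[s], h2[s]), s),
    )
    return Assignment(pair_id, best, (h1[best] + h2[best]) / 2.0)


def assign_sample(
    pairs: Iterable, index: ReferenceIndex, min_identity: float = MIN_IDENTITY
) -> list[Assignment]:
    """Align and assign every pair of one sample."""
    out = []
    for (id1, s1, _), (_, s2, _) in pairs:
        pair_id = id1.rsplit("/", 1)[0]
        out.append(
            assign_pair(
                pair_id,
                align_read(s1, index, min_identity),
                align_read(s2, index, min_identity),
            )
        )
    return out


@dataclass
class TaxonProfile:
    """Per-sample read counts at one rank, with derived proportions.

    Samples with zero assigned reads are flagged invalid and excluded from
    ``proportions``.
    """

    rank: str  # 'genus' or 'species'
    counts: pd.DataFrame  # samples x taxa, integer read counts
    unassigned: pd.Series

    @property
    def invalid_samples(self) -> list[str]:
        return [s for s in self.counts.index if self.counts.loc[s].sum() == 0]

    @property
    def proportions(self) -> pd.DataFrame:
        bad = self.invalid_samples
        if bad:
            warnings.warn(
                f"samples with zero assigned reads excluded from proportions: {bad}"
            )
        good = self.counts.drop(index=bad)
        return good.div(good.sum(axis=1), axis=0)


def build_profiles(
    assignments: Mapping[str, Sequence[Assignment]],
    taxonomy: Mapping[str, tuple[str, str]],
) -> tuple[TaxonProfile, TaxonProfile]:
    """Aggregate pair assignments into (genus, species) count profiles."""
    genus_counts: dict[str, dict[str, int]] = {}
    species_counts: dict[str, dict[str, int]] = {}
    unassigned: dict[str, int] = {}
    for sample, assigns in assignments.items():
        g: dict[str, int] = {}
        sp: dict[str, int] = {}
        n_un = 0
        for a in assigns:
            if a.seq_id is None:
                n_un += 1
                continue
            if a.seq_id not in taxonomy:
                raise KeyError(f"seq_id {a.seq_id!r} missing from taxonomy")
            genus, species = taxonomy[a.seq_id]
            g[genus] = g.get(genus, 0) + 1
            sp[species] = sp.get(species, 0) + 1
        genus_counts[sample] = g
        species_counts[sample] = sp
        unassigned[sample] = n_un
    gdf = pd.DataFrame(genus_counts).T.fillna(0).astype(int).sort_index(axis=1)
    sdf = pd.DataFrame(species_counts).T.fillna(0).astype(int).sort_index(axis=1)
    un = pd.Series(unassigned, name="unassigned")
    return (
        TaxonProfile("genus", gdf, un),
        TaxonProfile("species", sdf, un),
    )


def species_profile_on_reference(
    assignments: Mapping[str, Sequence[Assignment]], refdb: ReferenceDB
) -> pd.DataFrame:
    """Per-sample proportions over reference seq_ids (the tree's leaves)."""
    counts: dict[str, dict[str, int]] = {}
    for sample, assigns in assignments.items():
        c = dict.fromkeys(refdb.species_ids, 0)
        for a in assigns:
            if a.seq_id is not None:
                c[a.seq_id] += 1
        counts[sample] = c
    df = pd.DataFrame(counts).T[refdb.species_ids]
    totals = df.sum(axis=1)
    bad = totals[totals == 0].index.tolist()
    if bad:
        warnings.warn(f"samples with zero assigned reads dropped: {bad}")
        df = df.drop(index=bad)
        totals = totals.drop(index=bad)
    return df.div(totals, axis=0)


def group_minor_taxa(
    proportions: pd.DataFrame, min_mean_proportion: float
) -> pd.DataFrame:
    """Pool taxa with cohort-mean proportion below a threshold into 'Others'.

    Row sums are preserved. Refuses to pool every taxon.
    """
    if not 0.0 <= min_mean_proportion < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    if min_mean_proportion == 0.0:
        return proportions.copy()
    means = proportions.mean(axis=0)
    minor = [t for t in proportions.columns if means[t] < min_mean_proportion]
    if len(minor) == len(proportions.columns):
        raise ValueError("threshold would pool every taxon into 'Others'")
    if not minor:
        return proportions.copy()
    major = [t for t in proportions.columns if t not in minor]
    out = proportions[major].copy()
    out["Others"] = proportions[minor].sum(axis=1)
    return out


def profile_cohort(
    by_sample: Mapping[str, Iterable],
    refdb: ReferenceDB,
    k: int = 15,
    min_identity: float = MIN_IDENTITY,
):
    """QC-retained pairs -> (genus profile, species profile, leaf proportions)."""
    index = ReferenceIndex(refdb, k=k)
    assignments = {
        sample: assign_sample(pairs, index, min_identity)
        for sample, pairs in by_sample.items()
    }
    genus, species = build_profiles(assignments, refdb.taxonomy())
    leaf_props = species_profile_on_reference(assignments, refdb)
    return genus, species, leaf_props
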