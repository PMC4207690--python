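"""End-to-end orchestration: simulate -> qc -> profile -> cluster -> assoc -> classify.

One config and one master seed drive every stage; stage seeds are derived
deterministically with ``numpy.random.SeedSequence`` so reruns are
byte-identical and individual stages are reproducible in isolation. The run
produces a :class:`CohortReport` mirroring the study's result tables: cohort
genus means, typing summary with per-group normal fractions and Fisher
enrichment vs the predominant group, diversity comparisons, differential
abundance tables, co-occurrence networks, and classifier metrics.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import assoc, commtype, readqc, ruleclf, syndata, taxprof

__all__ = ["PipelineConfig", "CohortReport", "run", "summarize_typing"]


@dataclass
class PipelineConfig:
    """All stage parameters plus the global seed."""

    cohort: syndata.CohortConfig = field(default_factory=syndata.CohortConfig)
    qc_min_quality: int = 30
    qc_min_length: int = 100
    min_identity: float = 0.97
    kmer: int = 15
    k_range: tuple[int, int] = (2, 10)
    min_abnormal_case: int = 2
    abundance_min_proportion: float = 0.0025
    network_threshold: float = 0.4
    others_threshold: float = 0.01
    cv_folds: int = 5
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cohort = data.pop("cohort", None)
        cfg = cls(**data)
        if cohort is not None:
            unknown_c = set(cohort) - set(syndata.CohortConfig.__dataclass_fields__)
            if unknown_c:
                raise ValueError(f"unknown cohort config keys: {sorted(unknown_c)}")
            cfg.cohort = syndata.CohortConfig(**cohort)
        return cfg

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["k_range"] = list(self.k_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class CohortReport:
    """Aggregated results of one cohort run."""

    n_samples: int
    genus_means: dict
    typing: dict
    diversity_by_group: list
    diversity_by_class: list
    associations_genus: list
    associations_species: list
    network_edges: list
    casa_associations: list
    classifier: dict
    ari_vs_truth: float | None = None

    def check(self) -> None:
        sizes = self.typing.get("group_sizes", {})
        if sizes and sum(sizes.values()) != self.n_samples:
            raise AssertionError("group sizes do not sum to the cohort size")
        for g, frac in self.typing.get("normal_fraction", {}).items():
            n_norm = self.typing["normal_count"][g]
            if abs(frac - n_norm / sizes[g]) > 1e-12:
                raise AssertionError(f"normal fraction inconsistent for {g}")

    def to_json(self, path=None) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, pd.DataFrame):
                return o.to_dict()
            raise TypeError(f"not JSON-serializable: {type(o)}")

        text = json.dumps(dataclasses.asdict(self), indent=2, default=default, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def summarize_typing(labels: pd.Series, classes: pd.Series) -> dict:
    """Group sizes, normal fractions, and Fisher enrichment vs the predominant group.

    ``classes`` holds 'normal' / 'case' / 'excluded' per sample. For each
    group other than the one with the highest normal fraction, a 2x2 table
    (normal vs non-normal, that group vs the predominant group) gives a
    Fisher exact p-value and odds ratio.
    """
    groups = sorted(labels.unique())
    sizes = {g: int((labels == g).sum()) for g in groups}
    normal = classes.reindex(labels.index) == "normal"
    n_normal = {g: int(normal[labels == g].sum()) for g in groups}
    frac = {g: n_normal[g] / sizes[g] for g in groups}
    out = {
        "group_sizes": sizes,
        "normal_count": n_normal,
        "normal_fraction": frac,
    }
    if len(groups) < 2:
        return out
    predominant = max(groups, key=lambda g: (frac[g], g))
    tests = {}
    for g in groups:
        if g == predominant:
            continue
        table = [
            [n_normal[g], sizes[g] - n_normal[g]],
            [n_normal[predominant], sizes[predominant] - n_normal[predominant]],
        ]
        p, orx = assoc.fisher_or(table)
        tests[g] = {"vs": predominant, "p": p, "odds_ratio": orx, "table": table}
    out["predominant_group"] = predominant
    out["fisher_vs_predominant"] = tests
    return out


def run(
    config: PipelineConfig | None = None,
    outdir=None,
    cohort: syndata.SimulatedCohort | None = None,
) -> CohortReport:
    """Execute every stage on a synthetic cohort and assemble the report.

    If ``outdir`` is given, stage artifacts (TSV matrices, newick dendrogram,
    edge lists, report JSON) are written there. A pre-simulated ``cohort``
    may be supplied to reuse stage outputs across calls.
    """
    cfg = config or PipelineConfig()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- simulate ---------------------------------------------------------
    if cohort is None:
        cohort = syndata.simulate_cohort(cfg.cohort, seed=cfg.seed)
    refdb = cohort.refdb
    if out is not None:
        cohort.write(out / "simulated")

    # --- qc ---------------------------------------------------------------
    qc_cfg = readqc.QCConfig(min_quality=cfg.qc_min_quality, min_length=cfg.qc_min_length)
    all_pairs = [p for s in cohort.samples for p in s.pairs]
    by_sample, unassigned = readqc.demultiplex(all_pairs, cohort.barcode_map(), qc_cfg)
    retained, qc_report = readqc.run_qc(by_sample, qc_cfg, n_unassigned=len(unassigned))
    if out is not None:
        qc_report.to_frame().to_csv(out / "qc_report.tsv", sep="\t")

    # --- profile ----------------------------------------------------------
    genus_prof, species_prof, leaf_props = taxprof.profile_cohort(
        retained, refdb, k=cfg.kmer, min_identity=cfg.min_identity
    )
    genus_props = genus_prof.proportions
    if out is not None:
        genus_prof.counts.to_csv(out / "genus_counts.tsv", sep="\t")
        genus_props.to_csv(out / "genus_proportions.tsv", sep="\t")
        species_prof.counts.to_csv(out / "species_counts.tsv", sep="\t")

    # --- cluster ----------------------------------------------------------
    lo, hi = cfg.k_range
    typer = commtype.CommunityTyper(tree=refdb.tree(), k_range=(lo, hi))
    labels = typer.fit_predict(leaf_props)
    diversity = commtype.diversity_table(genus_prof.counts.loc[labels.index])
    div_group = commtype.compare_group_diversity(diversity, labels)
    if out is not None:
        pd.DataFrame(
            typer.distance_matrix_.data,
            index=typer.distance_matrix_.ids,
            columns=typer.distance_matrix_.ids,
        ).to_csv(out / "unifrac.tsv", sep="\t")
        Path(out / "dendrogram.nwk").write_text(typer.dendrogram_.to_newick() + "\n")
        coords, _ = commtype.pcoa(typer.distance_matrix_)
        coords.to_csv(out / "pcoa.tsv", sep="\t")

    # --- assoc ------------------------------------------------------------
    flags = {s.sample_id: assoc.flag_clinical(s.clinical) for s in cohort.samples}
    classes = assoc.define_classes(flags, min_abnormal_case=cfg.min_abnormal_case)
    classes = classes.reindex(labels.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        diff_genus = assoc.differential_abundance(
            genus_props, classes, rank="genus",
            min_proportion=cfg.abundance_min_proportion, alpha=cfg.alpha,
        )
        species_props = species_prof.proportions
        diff_species = assoc.differential_abundance(
            species_props, classes, rank="species",
            min_proportion=cfg.abundance_min_proportion, alpha=cfg.alpha,
        )
        net = assoc.spearman_network(genus_props, threshold=cfg.network_threshold)
        casa_df = pd.DataFrame(
            {sid: rec.casa for sid, rec in cohort.clinical_records().items()}
        ).T.reindex(labels.index)
        casa_res = assoc.casa_association(
            genus_props, casa_df,
            min_proportion=cfg.abundance_min_proportion, alpha=cfg.alpha,
        )
        div_class = commtype.compare_group_diversity(
            diversity.loc[classes[classes != "excluded"].index],
            classes[classes != "excluded"],
        )
    typing = summarize_typing(labels, classes)
    edges = [
        {"genus1": u, "genus2": v, "rho": d["rho"]} for u, v, d in net.edges(data=True)
    ]
    if out is not None:
        diff_genus.to_csv(out / "assoc_genus.tsv", sep="\t", index=False)
        diff_species.to_csv(out / "assoc_species.tsv", sep="\t", index=False)
        pd.DataFrame(edges).to_csv(out / "network_edges.tsv", sep="\t", index=False)
        casa_res.to_csv(out / "casa_associations.tsv", sep="\t", index=False)

    # --- classify ---------------------------------------------------------
    features = ruleclf.featurize_frame(genus_props)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv = ruleclf.evaluate_cv(
            features, labels.loc[features.index].to_numpy(),
            folds=cfg.cv_folds, seed=cfg.seed,
        )
        fixed_pred = ruleclf.FixedRuleClassifier().fit().predict(genus_props)
    fixed_agreement = float((fixed_pred == labels.loc[genus_props.index].to_numpy()).mean())
    classifier = {
        "auc": cv["auc"],
        "accuracy": cv["accuracy"],
        "confusion": cv["confusion"].to_dict(),
        "fixed_rule_agreement": fixed_agreement,
    }

    ari = None
    truth = cohort.true_labels().reindex(labels.index)
    if truth.notna().all():
        from sklearn.metrics import adjusted_rand_score

        ari = float(adjusted_rand_score(truth.to_numpy(), labels.to_numpy()))

    report = CohortReport(
        n_samples=len(labels),
        genus_means={g: float(m) for g, m in genus_props.mean().sort_values(ascending=False).items()},
        typing=typing,
        diversity_by_group=div_group.to_dict("records"),
        diversity_by_class=div_class.to_dict("records"),
        associations_genus=diff_genus.to_dict("records"),
        associations_species=diff_species.to_dict("records"),
        network_edges=edges,
        casa_associations=casa_res.to_dict("records"),
        classifier=classifier,
        ari_vs_truth=ari,
    )
    report.check()
    if out is not None:
        report.to_json(out / "report.json")
    return report
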