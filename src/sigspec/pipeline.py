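"""Orchestration: cohort filters and the end-to-end specificity study.

Stage order is fixed: catalog -> non-negative refit -> test-cohort size
filter & label harmonization -> Min-Max scaling (fit on training only) ->
SMOTE (training folds only) -> one model per cancer type x method ->
evaluation on the independent test cohort -> mismatched-cancer background
and negative-binomial p-values -> feature importance.  All randomness flows
from one top-level seed through named substreams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .collinearity import CorrelationReport, SimilaritySummary, sample_cosine_by_cancer, signature_correlation
from .containers import CohortLabels, ExposureMatrix, MotifCatalog, SignatureMatrix
from .ml import EvalMetrics, FeatureTable, ModelSpec, TrainedModel, evaluate, feature_importance, train_model
from .preprocess import minmax_apply, minmax_fit, smote_resample
from .refit import SignatureRefit
from .significance import BackgroundDistribution, background_f1, significance_table

logger = logging.getLogger(__name__)

DEFAULT_MIN_TEST_SAMPLES = 50
DEFAULT_METHODS = ("RF", "XGB", "MLP", "DNN", "NAS")

_SUBSTREAMS = ("smote", "split", "model", "nas", "importance")


def derive_seed(seed: int, stream: str, index: int = 0) -> int:
    """Named, collision-free substream seed below 2**31."""
    ss = np.random.SeedSequence([seed, _SUBSTREAMS.index(stream), index])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class FilterReport:
    dropped: pd.DataFrame  # (cancer_type, region, n) groups removed
    kept: pd.DataFrame


def filter_min_samples(
    labels: CohortLabels, min_n: int = DEFAULT_MIN_TEST_SAMPLES
) -> tuple[CohortLabels, FilterReport]:
    """Drop testing (cancer, region) groups with fewer than ``min_n`` samples.

    Training rows are never touched.  Raises if no test rows survive.
    """
    t = labels.table
    test = t[t["split"] == "test"]
    sizes = test.groupby(["cancer_type", "region"]).size().rename("n").reset_index()
    dropped = sizes[sizes["n"] < min_n]
    kept = sizes[sizes["n"] >= min_n]
    bad_keys = set(map(tuple, dropped[["cancer_type", "region"]].to_numpy()))
    keep_mask = (t["split"] == "train") | ~t.apply(
        lambda row: (row["cancer_type"], row["region"]) in bad_keys, axis=1
    )
    out = labels.subset(keep_mask)
    if not (out.table["split"] == "test").any():
        raise ValueError(f"no testing groups with at least {min_n} samples remain")
    for _, row in dropped.iterrows():
        logger.info(
            "dropping test group %s/%s (n=%d < %d)",
            row["cancer_type"], row["region"], row["n"], min_n,
        )
    return out, FilterReport(dropped.reset_index(drop=True), kept.reset_index(drop=True))


def harmonize_labels(
    train_labels: CohortLabels, test_labels: CohortLabels
) -> tuple[CohortLabels, CohortLabels, pd.DataFrame]:
    """Keep only cancer types present in both splits; report exclusions."""
    train_types = set(train_labels.table["cancer_type"])
    test_types = set(test_labels.table["cancer_type"])
    common = train_types & test_types
    if not common:
        raise ValueError("no cancer types shared between training and testing")
    report = pd.DataFrame(
        {
            "cancer_type": sorted(train_types | test_types),
        }
    )
    report["in_train"] = report["cancer_type"].isin(train_types)
    report["in_test"] = report["cancer_type"].isin(test_types)
    report["kept"] = report["cancer_type"].isin(common)
    out_train = train_labels.subset(train_labels.table["cancer_type"].isin(common))
    out_test = test_labels.subset(test_labels.table["cancer_type"].isin(common))
    n_excluded = (len(train_labels.table) - len(out_train.table)) + (
        len(test_labels.table) - len(out_test.table)
    )
    if n_excluded:
        logger.info("harmonize_labels: excluded %d samples outside the common label space",
                    n_excluded)
    return out_train, out_test, report


def _exposure_features(
    e: ExposureMatrix, sample_ids: list[str], binary: bool
) -> np.ndarray:
    df = e.to_frame()[sample_ids]
    X = df.to_numpy().T  # samples x signatures
    if binary:
        from .refit import dichotomize

        sub = ExposureMatrix(e.signature_ids, sample_ids, df.to_numpy())
        X = dichotomize(sub).values.T.astype(float)
    return X


@dataclass
class StudyResults:
    """Everything the specificity study computes, plus provenance."""

    model: "SpecificityStudy"
    exposures_train: ExposureMatrix
    exposures_test: ExposureMatrix
    correlation: CorrelationReport
    similarity: SimilaritySummary
    metrics: pd.DataFrame
    significance: pd.DataFrame
    backgrounds: Mapping[str, BackgroundDistribution]
    importances: dict[tuple[str, str], list[tuple[str, float]]]
    models: dict[tuple[str, str], TrainedModel]
    matched_metrics: list[tuple[str, str, str, EvalMetrics]]
    config_echo: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Mutational-signature cancer-specificity study",
            "=" * 46,
            f"methods:           {', '.join(self.config_echo.get('methods', []))}",
            f"cancer types:      {', '.join(self.config_echo.get('cancer_types', []))}",
            f"seed:              {self.config_echo.get('seed')}",
            "",
            "Top models by F1 (independent test):",
        ]
        top = self.metrics.sort_values("f1", ascending=False).head(8)
        for _, r in top.iterrows():
            lines.append(
                f"  {r.cancer_type:<8} {r.region:<4} {r.method:<4} "
                f"precision={r.precision:.2f} recall={r.recall:.2f} "
                f"f1={r.f1:.2f} auc={r.auc:.2f}"
            )
        n_sig = int(self.significance["significant"].sum()) if len(self.significance) else 0
        lines += ["", f"models significant vs mismatched-cancer background (p<0.05): {n_sig}"]
        return "\n".join(lines)

    def save(self, directory) -> None:
        from .io import write_exposures

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_exposures(self.exposures_train, directory / "exposures_train.tsv")
        write_exposures(self.exposures_test, directory / "exposures_test.tsv")
        self.correlation.matrix.to_csv(directory / "signature_correlation.tsv", sep="\t")
        self.correlation.pairs.to_csv(
            directory / "correlated_pairs.tsv", sep="\t", index=False
        )
        self.similarity.table.to_csv(directory / "sample_cosine_summary.tsv", sep="\t")
        self.metrics.to_csv(directory / "metrics.tsv", sep="\t", index=False)
        self.significance.to_csv(directory / "significance.tsv", sep="\t", index=False)
        bg_rows = [
            {"method": method, "model_cancer": a, "test_cancer": b, "f1": s}
            for method, bg in self.backgrounds.items()
            for (a, b), s in zip(bg.pairs, bg.scores)
        ]
        pd.DataFrame(bg_rows).to_csv(directory / "background_f1.tsv", sep="\t", index=False)
        imp_rows = [
            {"cancer_type": c, "method": m, "rank": i + 1, "feature": f, "importance": v}
            for (c, m), ranking in self.importances.items()
            for i, (f, v) in enumerate(ranking)
        ]
        pd.DataFrame(imp_rows).to_csv(
            directory / "feature_importance.tsv", sep="\t", index=False
        )
        (directory / "config_echo.yaml").write_text(
            yaml.safe_dump(self.config_echo, sort_keys=False)
        )


class SpecificityStudy:
    """One-vs-rest cancer-type specificity study on refitted exposures.

    Built from a training and an independent testing cohort (catalogs plus
    labels) and a reference signature panel; ``fit()`` runs the whole
    pipeline and returns a :class:`StudyResults`.
    """

    def __init__(
        self,
        signatures: SignatureMatrix,
        train_catalog: MotifCatalog,
        train_labels: CohortLabels,
        test_catalog: MotifCatalog,
        test_labels: CohortLabels,
        methods: tuple[str, ...] = DEFAULT_METHODS,
        seed: int = 0,
        min_test_samples: int = DEFAULT_MIN_TEST_SAMPLES,
        binary_features: bool = False,
        nas_budget: int = 25,
        compute_importance: bool = True,
    ):
        self.signatures = signatures
        self.train_catalog = train_catalog
        self.train_labels = train_labels
        self.test_catalog = test_catalog
        self.test_labels = test_labels
        self.methods = tuple(ModelSpec(m).method for m in methods)
        self.seed = seed
        self.min_test_samples = min_test_samples
        self.binary_features = binary_features
        self.nas_budget = nas_budget
        self.compute_importance = compute_importance

    @classmethod
    def from_scenario(cls, bundle, **kwargs) -> "SpecificityStudy":
        return cls(
            signatures=bundle.signatures,
            train_catalog=bundle.train_catalog,
            train_labels=bundle.train_truth.labels,
            test_catalog=bundle.test_catalog,
            test_labels=bundle.test_truth.labels,
            **kwargs,
        )

    # ------------------------------------------------------------------
    def fit(self) -> StudyResults:
        logger.info("refit: %d train / %d test samples, %d signatures",
                    self.train_catalog.n_samples, self.test_catalog.n_samples,
                    self.signatures.n_signatures)
        refit_train = SignatureRefit(self.train_catalog, self.signatures).fit()
        refit_test = SignatureRefit(self.test_catalog, self.signatures).fit()

        test_labels, filter_report = filter_min_samples(
            self.test_labels, self.min_test_samples
        )
        train_labels, test_labels, harmonize_report = harmonize_labels(
            self.train_labels, test_labels
        )
        train_ids = train_labels.sample_ids
        test_ids = test_labels.sample_ids
        cancer_types = sorted(
            set(train_labels.table["cancer_type"]) & set(test_labels.table["cancer_type"])
        )
        logger.info("common cancer types: %s", cancer_types)

        X_train_raw = _exposure_features(
            refit_train.exposures, train_ids, self.binary_features
        )
        X_test_raw = _exposure_features(
            refit_test.exposures, test_ids, self.binary_features
        )
        scaler = minmax_fit(X_train_raw)
        X_train = minmax_apply(scaler, X_train_raw)
        X_test = minmax_apply(scaler, X_test_raw)
        feature_ids = list(self.signatures.signature_ids)

        y_train_type = train_labels.table.loc[train_ids, "cancer_type"].to_numpy()
        y_test_type = test_labels.table.loc[test_ids, "cancer_type"].to_numpy()
        test_region = {
            c: "+".join(
                sorted(set(test_labels.table[test_labels.table["cancer_type"] == c]["region"]))
            )
            for c in cancer_types
        }

        models: dict[tuple[str, str], TrainedModel] = {}
        matched: list[tuple[str, str, str, EvalMetrics]] = []
        test_tables: dict[str, FeatureTable] = {}
        metrics_rows = []
        for ci, cancer in enumerate(cancer_types):
            y_tr = (y_train_type == cancer).astype(int)
            y_te = (y_test_type == cancer).astype(int)
            ft_test = FeatureTable(X_test, y_te, test_ids, feature_ids)
            test_tables[cancer] = ft_test
            Xb, yb = smote_resample(
                X_train, y_tr, seed=derive_seed(self.seed, "smote", ci)
            )
            ids_b = train_ids + [f"synthetic_{i}" for i in range(len(yb) - len(y_tr))]
            ft_train = FeatureTable(Xb, yb, ids_b, feature_ids)
            for mi, method in enumerate(self.methods):
                hp = {"budget": self.nas_budget} if method == "NAS" else {}
                spec = ModelSpec(
                    method,
                    seed=derive_seed(self.seed, "model", ci * 100 + mi),
                    hyperparameters=hp,
                )
                logger.info("training %s / %s", cancer, method)
                model = train_model(spec, ft_train)
                models[(cancer, method)] = model
                m = evaluate(model, ft_test)
                matched.append((cancer, test_region[cancer], method, m))
                metrics_rows.append(
                    {
                        "cancer_type": cancer,
                        "region": test_region[cancer],
                        "method": method,
                        "precision": m.precision,
                        "recall": m.recall,
                        "f1": m.f1,
                        "accuracy": m.accuracy,
                        "auc": m.auc,
                        "n_positive": m.n_positive,
                    }
                )
        metrics = pd.DataFrame(metrics_rows)

        backgrounds: dict[str, BackgroundDistribution] = {}
        for method in self.methods:
            backgrounds[method] = background_f1(
                {c: models[(c, method)] for c in cancer_types}, test_tables
            )
        sig_table = significance_table(matched, backgrounds)

        importances: dict[tuple[str, str], list[tuple[str, float]]] = {}
        if self.compute_importance:
            for idx, ((cancer, method), model) in enumerate(models.items()):
                importances[(cancer, method)] = feature_importance(
                    model, test_tables[cancer], seed=derive_seed(self.seed, "importance", idx)
                )

        correlation = signature_correlation(refit_train.exposures)
        all_labels = CohortLabels(
            pd.concat([train_labels.table, test_labels.table])
        )
        exp_all = ExposureMatrix(
            feature_ids,
            train_ids + test_ids,
            np.hstack(
                [
                    refit_train.exposures.to_frame()[train_ids].to_numpy(),
                    refit_test.exposures.to_frame()[test_ids].to_numpy(),
                ]
            ),
        )
        similarity = sample_cosine_by_cancer(exp_all, all_labels)

        config_echo = {
            "seed": self.seed,
            "methods": list(self.methods),
            "cancer_types": cancer_types,
            "min_test_samples": self.min_test_samples,
            "binary_features": self.binary_features,
            "nas_budget": self.nas_budget,
            "n_train": len(train_ids),
            "n_test": len(test_ids),
            "dropped_test_groups": filter_report.dropped.to_dict("records"),
            "harmonization": harmonize_report.to_dict("records"),
        }
        return StudyResults(
            model=self,
            exposures_train=refit_train.exposures,
            exposures_test=refit_test.exposures,
            correlation=correlation,
            similarity=similarity,
            metrics=metrics,
            significance=sig_table,
            backgrounds=backgrounds,
            importances=importances,
            models=models,
            matched_metrics=matched,
            config_echo=config_echo,
        )


def run_analysis(config: dict) -> StudyResults:
    """Run the full pipeline from a configuration mapping.

    Recognized keys: ``scenario`` (name of a synthetic benchmark) or the
    file paths ``signatures``, ``train_catalog``/``train_maf``,
    ``test_catalog``/``test_maf``, ``train_labels``, ``test_labels``;
    plus ``methods``, ``seed``, ``min_test_samples``, ``binary_features``,
    ``nas_budget``, ``out_dir``.
    """
    from . import io as sio

    seed = int(config.get("seed", 0))
    methods = tuple(config.get("methods", DEFAULT_METHODS))
    kwargs = dict(
        methods=methods,
        seed=seed,
        min_test_samples=int(config.get("min_test_samples", DEFAULT_MIN_TEST_SAMPLES)),
        binary_features=bool(config.get("binary_features", False)),
        nas_budget=int(config.get("nas_budget", 25)),
    )
    if "scenario" in config:
        from .synthetic import make_benchmark_scenario

        bundle = make_benchmark_scenario(
            config["scenario"],
            seed=seed,
            **{
                k: config[k]
                for k in ("K", "n_per_type", "n_mut_mean")
                if k in config
            },
        )
        study = SpecificityStudy.from_scenario(bundle, **kwargs)
    else:
        required = ("signatures", "train_catalog", "test_catalog", "train_labels", "test_labels")
        missing = [k for k in required if k not in config]
        if missing:
            raise ValueError(
                f"configuration must provide a 'scenario' or the file paths {missing}"
            )
        study = SpecificityStudy(
            signatures=sio.read_signature_matrix(config["signatures"]),
            train_catalog=sio.read_catalog(config["train_catalog"]),
            train_labels=sio.read_labels(config["train_labels"]),
            test_catalog=sio.read_catalog(config["test_catalog"]),
            test_labels=sio.read_labels(config["test_labels"]),
            **kwargs,
        )
    results = study.fit()
    if "out_dir" in config:
        results.save(config["out_dir"])
    return results
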