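"""Resampling cross-validation grids, blind testing and the full pipeline.

Monte-Carlo cross-validation draws a stated proportion of individuals from
each population (stratified, without replacement) as training data, ranks
loci by Fst *on the training data only*, fits the classifier on the top
locus fraction and scores the held-out individuals; each (proportion,
fraction) cell is resampled ``n_resamples`` times.  With the default grid of
three proportions x four locus fractions x 30 resamples this is 360
assignment tests.

K-fold cross-validation partitions each population into K nearly equal
groups (stratified, shuffled once per K); every group is predicted by a
model trained on the other K-1, for each locus fraction.  With K in
{3, 4, 5} and four fractions this is 48 assignment tests, and each
individual's membership probability is aggregated across the runs in which
it was held out.

Locus ranking always happens inside the resample/fold on training data
only — anything else would leak test information into feature selection.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    AssignmentResult,
    ClassifierConfig,
    assign_individuals,
    fit_classifier,
    membership_probabilities,
)
from .distance import distance_summaries, pairwise_distance_matrix, pair_values, separation_report
from .markers import (
    allele_frequencies,
    differential_summary,
    qc_filter_loci,
    select_top_fst_loci,
    success_summary,
)
from .panel import GenotypeMatrix, load_bundled_panel
from .simulate import SimulationConfig, simulate_population

__all__ = ["CvConfig", "CvReport", "monte_carlo_cv", "kfold_cv", "blind_test", "run_full_validation"]

logger = logging.getLogger("canisnp")


@dataclass
class CvConfig:
    """Configuration of one cross-validation experiment grid."""

    mode: str = "monte_carlo"  # or "kfold"
    train_proportions: Sequence[float] = (0.5, 0.7, 0.9)
    locus_fractions: Sequence[float] = (0.10, 0.25, 0.50, 1.0)
    n_resamples: int = 30
    k_values: Sequence[int] = (3, 4, 5)
    model: Optional[ClassifierConfig] = None
    seed: int = 0

    def expected_tests(self) -> int:
        if self.mode == "monte_carlo":
            return self.n_resamples * len(self.train_proportions) * len(self.locus_fractions)
        return sum(self.k_values) * len(self.locus_fractions)


@dataclass
class CvCell:
    """One assignment test: a fitted model scored on one held-out set."""

    train_proportion: Optional[float]
    k: Optional[int]
    fold: Optional[int]
    resample: Optional[int]
    locus_fraction: float
    selected_loci: tuple[str, ...]
    accuracies: dict[str, float]
    n_test: dict[str, int]
    test_ids: tuple[str, ...] = ()
    memberships: list[AssignmentResult] = field(default_factory=list)


@dataclass
class CvReport:
    mode: str
    config: CvConfig
    cells: list[CvCell]

    @property
    def total_tests(self) -> int:
        return len(self.cells)

    def accuracy_table(self) -> pd.DataFrame:
        """Mean +/- SD per-population accuracy per grid cell."""
        rows = []
        for cell in self.cells:
            for pop, acc in cell.accuracies.items():
                rows.append(
                    {
                        "train_proportion": cell.train_proportion,
                        "k": cell.k,
                        "locus_fraction": cell.locus_fraction,
                        "population": pop,
                        "accuracy": acc,
                    }
                )
        long = pd.DataFrame(rows)
        group_key = "train_proportion" if self.mode == "monte_carlo" else "k"
        return (
            long.groupby([group_key, "locus_fraction", "population"])["accuracy"]
            .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n="count")
            .reset_index()
        )

    def membership_table(self) -> pd.DataFrame:
        """Per-individual held-out membership probabilities (kfold mode)."""
        rows = []
        for cell in self.cells:
            for r in cell.memberships:
                for pop, p in r.membership.items():
                    rows.append(
                        {
                            "individual_id": r.individual_id,
                            "k": cell.k,
                            "locus_fraction": cell.locus_fraction,
                            "population": pop,
                            "membership": p,
                            "predicted": r.predicted,
                        }
                    )
        return pd.DataFrame(rows)

    def correct_membership_summary(self, true_labels: Mapping[str, str]) -> pd.DataFrame:
        """Mean +/- SD membership in the *true* population, per population."""
        tbl = self.membership_table()
        tbl["true"] = tbl["individual_id"].map(dict(true_labels))
        correct = tbl[tbl["population"] == tbl["true"]]
        return (
            correct.groupby("true")["membership"]
            .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n="count")
            .reset_index()
        )


def _default_model(mode: str) -> ClassifierConfig:
    # LDA builds the Monte-Carlo predictive models; naive Bayes produces
    # membership probabilities for K-fold and blind tests.
    if mode == "monte_carlo":
        return ClassifierConfig(model="lda")
    return ClassifierConfig(model="naive_bayes")


def _rank_training_loci(train: GenotypeMatrix):
    """Fst statistics computed on training data only (no test leakage)."""
    freqs = allele_frequencies(train)
    pops = freqs.populations
    stats, _ = differential_summary(freqs, pops[0], pops[1])
    return stats


def _fit_top_fraction(
    train: GenotypeMatrix, stats, fraction: float, base_config: ClassifierConfig
):
    subset = select_top_fst_loci(stats, fraction)
    config = dataclasses.replace(base_config, locus_subset=subset)
    return fit_classifier(train, config), tuple(subset)


def _score(model, test: GenotypeMatrix) -> tuple[dict, dict, list[AssignmentResult]]:
    results = membership_probabilities(model, test)
    truth = test.populations.to_dict()
    _, acc = assign_individuals(results, truth)
    n_test = test.population_counts()
    acc_by_pop = {p: acc[p] for p in n_test}
    return acc_by_pop, n_test, results


def monte_carlo_cv(reference: GenotypeMatrix, config: CvConfig) -> CvReport:
    """Monte-Carlo cross-validation over the proportion x locus-fraction grid."""
    model_cfg = config.model or _default_model("monte_carlo")
    pops = sorted(reference.populations.unique())
    ids_by_pop = {
        p: np.array(reference.dosage.index[reference.populations == p]) for p in pops
    }
    for prop in config.train_proportions:
        for p, ids in ids_by_pop.items():
            n_train = int(round(prop * len(ids)))
            if n_train < 2 or n_train >= len(ids):
                raise ValueError(
                    f"training proportion {prop} leaves no usable test set for {p!r}"
                )
    rng = np.random.default_rng(config.seed)
    cells: list[CvCell] = []
    for prop in config.train_proportions:
        for resample in range(config.n_resamples):
            train_ids: list[str] = []
            test_ids: list[str] = []
            for p in pops:
                ids = ids_by_pop[p]
                n_train = int(round(prop * len(ids)))
                perm = rng.permutation(len(ids))
                train_ids.extend(ids[perm[:n_train]])
                test_ids.extend(ids[perm[n_train:]])
            assert not set(train_ids) & set(test_ids)
            train = reference.subset_individuals(train_ids)
            test = reference.subset_individuals(test_ids)
            stats = _rank_training_loci(train)
            for fraction in config.locus_fractions:
                model, subset = _fit_top_fraction(train, stats, fraction, model_cfg)
                acc, n_test, _ = _score(model, test)
                cells.append(
                    CvCell(
                        train_proportion=prop,
                        k=None,
                        fold=None,
                        resample=resample,
                        locus_fraction=fraction,
                        selected_loci=subset,
                        accuracies=acc,
                        n_test=n_test,
                        test_ids=tuple(test_ids),
                    )
                )
    return CvReport(mode="monte_carlo", config=config, cells=cells)


def _stratified_folds(
    ids_by_pop: Mapping[str, np.ndarray], k: int, rng: np.random.Generator
) -> list[list[str]]:
    """K stratified folds; per-population fold sizes differ by at most one."""
    folds: list[list[str]] = [[] for _ in range(k)]
    for p in sorted(ids_by_pop):
        ids = ids_by_pop[p]
        if k > len(ids):
            raise ValueError(f"k={k} exceeds population size {len(ids)} for {p!r}")
        perm = rng.permutation(len(ids))
        for fold_idx, chunk in enumerate(np.array_split(ids[perm], k)):
            folds[fold_idx].extend(chunk)
    return folds


def kfold_cv(reference: GenotypeMatrix, config: CvConfig) -> CvReport:
    """Stratified K-fold cross-validation with per-individual memberships."""
    model_cfg = config.model or _default_model("kfold")
    pops = sorted(reference.populations.unique())
    ids_by_pop = {
        p: np.array(reference.dosage.index[reference.populations == p]) for p in pops
    }
    rng = np.random.default_rng(config.seed)
    cells: list[CvCell] = []
    for k in config.k_values:
        folds = _stratified_folds(ids_by_pop, k, rng)
        for fold_idx in range(k):
            test_ids = folds[fold_idx]
            train_ids = [i for j, f in enumerate(folds) if j != fold_idx for i in f]
            assert not set(train_ids) & set(test_ids)
            train = reference.subset_individuals(train_ids)
            test = reference.subset_individuals(test_ids)
            stats = _rank_training_loci(train)
            for fraction in config.locus_fractions:
                model, subset = _fit_top_fraction(train, stats, fraction, model_cfg)
                acc, n_test, results = _score(model, test)
                cells.append(
                    CvCell(
                        train_proportion=None,
                        k=k,
                        fold=fold_idx,
                        resample=None,
                        locus_fraction=fraction,
                        selected_loci=subset,
                        accuracies=acc,
                        n_test=n_test,
                        test_ids=tuple(test_ids),
                        memberships=results,
                    )
                )
    return CvReport(mode="kfold", config=config, cells=cells)


def blind_test(
    reference: GenotypeMatrix,
    query: GenotypeMatrix,
    config: Optional[ClassifierConfig] = None,
) -> tuple[list[AssignmentResult], pd.DataFrame]:
    """Assign query individuals with a model fitted on the full reference.

    Query population labels are ignored for prediction; when present (i.e.
    not 'unknown') they drive the correctness summary: per true population,
    the count assigned correctly and the mean +/- SD membership in the
    correct and in the wrong class.
    """
    config = config or ClassifierConfig(model="naive_bayes")
    model = fit_classifier(reference, config)
    results = membership_probabilities(model, query)
    known = query.populations[query.populations != "unknown"]
    rows = []
    for pop in sorted(known.unique()):
        ids = set(known.index[known == pop])
        sub = [r for r in results if r.individual_id in ids]
        correct = [r.membership[pop] for r in sub]
        wrong = [1.0 - r.membership[pop] for r in sub]
        rows.append(
            {
                "population": pop,
                "n": len(sub),
                "n_correct": sum(r.predicted == pop for r in sub),
                "mean_membership_correct": float(np.mean(correct)) if sub else 0.0,
                "sd_membership_correct": float(np.std(correct, ddof=1)) if len(sub) > 1 else 0.0,
                "mean_membership_wrong": float(np.mean(wrong)) if sub else 0.0,
                "sd_membership_wrong": float(np.std(wrong, ddof=1)) if len(sub) > 1 else 0.0,
            }
        )
    return results, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

DEFAULT_STAGES = ("qc", "stats", "distances", "monte_carlo", "kfold", "blind")


def _child_seeds(seed: int, n: int) -> list[int]:
    # keep derived seeds in signed-int32 range for portability of manifests
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def _build_reference(spec: Mapping, freqs, seed: int) -> GenotypeMatrix:
    from .io import read_genotype_table  # local import to avoid cycle at module load

    source = spec.get("source", "simulate")
    if source == "file":
        panel = freqs.panel
        return read_genotype_table(spec["path"], panel, format=spec.get("format", "csv"))
    sizes = spec.get("n", {"wolf": 80, "dog": 90})
    mode = spec.get("mode", "genotype_freq")
    parts = []
    for i, (pop, n) in enumerate(sorted(sizes.items())):
        parts.append(
            simulate_population(
                freqs, SimulationConfig(population=pop, n_individuals=int(n),
                                        mode=mode, seed=seed + i)
            )
        )
    return GenotypeMatrix.concat(parts)


def run_full_validation(config, output_dir=None) -> dict:
    """Run the configured validation stages end to end.

    ``config`` is a mapping or a path to a YAML/JSON file with keys
    ``seed``, ``reference``, ``blind``, ``stages``, ``cv`` and
    ``qc_threshold``.  Writes one CSV/JSON per stage plus a run manifest
    when ``output_dir`` is given, and returns the in-memory bundle.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config or {})
    seed = int(config.get("seed", 0))
    stages = tuple(config.get("stages", DEFAULT_STAGES))
    seeds = _child_seeds(seed, 6)
    logger.info("run_full_validation seed=%d child_seeds=%s stages=%s", seed, seeds, stages)

    panel, freqs, success = load_bundled_panel()
    bundle: dict = {
        "manifest": {
            "version": __version__,
            "seed": seed,
            "child_seeds": seeds,
            "stages": list(stages),
            "config": {k: v for k, v in config.items() if k != "stages"},
        }
    }
    current_stage = "setup"
    try:
        current_stage = "qc"
        if "qc" in stages:
            decisions = qc_filter_loci(success, float(config.get("qc_threshold", 0.90)))
            retained = [d.locus_id for d in decisions if d.retained]
            bundle["qc"] = {
                "decisions": [dataclasses.asdict(d) for d in decisions],
                "retained": retained,
                "success_summary": success_summary(success, retained),
            }

        current_stage = "reference"
        reference = _build_reference(config.get("reference", {}), freqs, seeds[0])
        pops = sorted(reference.populations.unique())

        current_stage = "stats"
        if "stats" in stages:
            stats, summary = differential_summary(freqs, pops[0], pops[1])
            bundle["stats"] = {
                "per_locus": pd.DataFrame(
                    {
                        "locus_id": [s.locus_id for s in stats],
                        "between_differential": [s.between_differential for s in stats],
                        "fst": [s.fst for s in stats],
                    }
                ),
                "summary": summary,
            }

        current_stage = "distances"
        if "distances" in stages:
            dist = pairwise_distance_matrix(reference)
            summaries = distance_summaries(dist, reference.populations)
            parts = pair_values(dist, reference.populations)
            rep = separation_report(parts["intra_overall"], parts["inter"])
            bundle["distances"] = {
                "summaries": {k: dataclasses.asdict(v) for k, v in summaries.items()},
                "separation": dataclasses.asdict(rep),
            }

        current_stage = "monte_carlo"
        if "monte_carlo" in stages:
            cv = dict(config.get("cv", {}))
            mc_config = CvConfig(
                mode="monte_carlo",
                train_proportions=tuple(cv.get("train_proportions", (0.5, 0.7, 0.9))),
                locus_fractions=tuple(cv.get("locus_fractions", (0.10, 0.25, 0.50, 1.0))),
                n_resamples=int(cv.get("n_resamples", 30)),
                seed=seeds[1],
            )
            report = monte_carlo_cv(reference, mc_config)
            bundle["monte_carlo"] = {
                "total_tests": report.total_tests,
                "accuracy": report.accuracy_table(),
            }

        current_stage = "kfold"
        if "kfold" in stages:
            cv = dict(config.get("cv", {}))
            kf_config = CvConfig(
                mode="kfold",
                k_values=tuple(cv.get("k_values", (3, 4, 5))),
                locus_fractions=tuple(cv.get("locus_fractions", (0.10, 0.25, 0.50, 1.0))),
                seed=seeds[2],
            )
            report = kfold_cv(reference, kf_config)
            bundle["kfold"] = {
                "total_tests": report.total_tests,
                "accuracy": report.accuracy_table(),
                "correct_membership": report.correct_membership_summary(
                    reference.populations.to_dict()
                ),
            }

        current_stage = "blind"
        if "blind" in stages:
            blind_spec = dict(config.get("blind", {"n": {"wolf": 17, "dog": 18}}))
            query = _build_reference(blind_spec, freqs, seeds[3])
            results, summary = blind_test(reference, query)
            frame, _ = assign_individuals(results)
            bundle["blind"] = {"assignments": frame, "summary": summary}
    except Exception as exc:
        raise RuntimeError(f"validation stage {current_stage!r} failed: {exc}") from exc

    if output_dir is not None:
        _write_bundle(bundle, Path(output_dir))
    return bundle


def _write_bundle(bundle: Mapping, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)

    def _jsonable(obj):
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict(orient="records")
        if isinstance(obj, dict):
            return {k: _jsonable(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_jsonable(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    for stage, content in bundle.items():
        if isinstance(content, dict):
            for key, value in content.items():
                if isinstance(value, pd.DataFrame):
                    value.to_csv(outdir / f"{stage}_{key}.csv", index=False)
        with open(outdir / f"{stage}.json", "w") as fh:
            json.dump(_jsonable(content), fh, indent=2, default=str)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(_jsonable(bundle), fh, indent=2, default=str)
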