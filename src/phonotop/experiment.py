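"""Comparative experiment harness: baseline recognizers vs GA-optimized
per-phoneme topologies on synthetic speaker cohorts.

For each synthetic speaker the harness trains the uniform-topology
baseline systems (Bakis-1 with 3 states, Bakis-2 with 4, Ergodic with 3,
all at the baseline mixture count) under one of three training schemes —
pooling all speakers' training data, the target speaker only, or pooling
within the speaker's severity group — scores them on the speaker's test
split, runs the micro-GA on the training/fitness splits, and reports the
baseline-vs-optimized comparison together with a matched-pairs
significance test over per-sentence error counts.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import Corpus
from .decoder import AlignmentResult, compile_network, score_corpus
from .ga import GAConfig, make_codec, run_micro_ga
from .simulate import Cohort, TruthSpec, make_cohort
from .topology import BAKIS1, BAKIS2, ERGODIC
from .training import TrainConfig, train_recognizer, uniform_assignment

logger = logging.getLogger(__name__)

SCHEMES = ("scheme1_all_speakers", "scheme2_target_only", "dysarthria_specific")

#: Baseline system name → (topology code, state count), the three uniform
#: systems seeded into the optimizer's initial population.
BASELINE_SYSTEMS: dict[str, tuple[int, int]] = {
    "bakis1_3": (BAKIS1, 3),
    "bakis2_4": (BAKIS2, 4),
    "ergodic_3": (ERGODIC, 3),
}


@dataclass(frozen=True)
class ExperimentConfig:
    truth: TruthSpec = TruthSpec()
    n_speakers: int = 10
    severity_levels: tuple[str, ...] | None = None
    n_nouns: int = 74
    n_verbs: int = 37
    n_sentences: int = 74
    fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    scheme: str = "dysarthria_specific"
    baseline_systems: tuple[str, ...] = ("bakis1_3", "bakis2_4", "ergodic_3")
    baseline_mixtures: int = 6
    ga: GAConfig = field(default_factory=GAConfig)

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        unknown = set(self.baseline_systems) - set(BASELINE_SYSTEMS)
        if unknown:
            raise ValueError(f"unknown baseline system(s): {sorted(unknown)}")
        if not (1 <= self.baseline_mixtures <= 16):
            raise ValueError("baseline mixtures must lie in [1, 16]")


# ---------------------------------------------------------------------------
# matched-pairs significance test
# ---------------------------------------------------------------------------

@dataclass
class MatchedPairsResult:
    p_value: float
    statistic: float  # total error-count difference (baseline − comparison)
    n_pairs: int
    exact: bool


def matched_pairs_test(
    baseline_errors: list[int] | list[AlignmentResult],
    comparison_errors: list[int] | list[AlignmentResult],
    seed: int = 0,
    n_resamples: int = 10_000,
    exact_threshold: int = 12,
) -> MatchedPairsResult:
    """Two-sided sign-flip permutation test on paired per-sentence error
    counts from the same test set.

    The statistic is the summed difference of error counts; its null
    distribution is generated by flipping the sign of each sentence's
    difference.  All 2^n assignments are enumerated for small n (always
    when n < 6, with a warning), otherwise ``n_resamples`` random flips
    are drawn.
    """
    base = [e.errors if isinstance(e, AlignmentResult) else e for e in baseline_errors]
    comp = [e.errors if isinstance(e, AlignmentResult) else e for e in comparison_errors]
    if len(base) != len(comp) or not base:
        raise ValueError("paired, non-empty error lists required")
    d = np.asarray(base, dtype=float) - np.asarray(comp, dtype=float)
    n = len(d)
    stat = float(d.sum())
    if n < 6:
        warnings.warn(
            f"only {n} pairs; using exact enumeration", stacklevel=2
        )
    exact = n <= exact_threshold or n < 6
    if exact:
        hits = total = 0
        for signs in itertools.product((1.0, -1.0), repeat=n):
            total += 1
            if abs(float(np.dot(signs, d))) >= abs(stat) - 1e-12:
                hits += 1
        p = hits / total
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_resamples, n))
        null = np.abs(signs @ d)
        p = float(np.mean(null >= abs(stat) - 1e-12))
    return MatchedPairsResult(p_value=p, statistic=stat, n_pairs=n, exact=exact)


# ---------------------------------------------------------------------------
# experiment harness
# ---------------------------------------------------------------------------

@dataclass
class ExperimentReport:
    comparison: pd.DataFrame   # speaker, severity, system, fitness/test WAcc
    assignments: dict[str, pd.DataFrame]
    convergence: dict[str, pd.DataFrame]
    significance: pd.DataFrame
    cohort: Cohort


def _scheme_train_corpus(
    cohort: Cohort, target_idx: int, scheme: str
) -> Corpus:
    target = cohort.speakers[target_idx]
    if scheme == "scheme2_target_only":
        pool = [target]
    elif scheme == "scheme1_all_speakers":
        pool = cohort.speakers
    else:  # dysarthria_specific: pool within the severity group
        pool = [s for s in cohort.speakers if s.severity == target.severity]
    sentences = []
    for spk in pool:
        sentences.extend(spk.corpus.subset("train").sentences)
    return Corpus(sentences)


def run_experiment(
    config: ExperimentConfig,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> ExperimentReport:
    """Full comparative run on one synthetic cohort.

    Per speaker: every configured baseline system is trained under the
    chosen scheme and scored on the speaker's test split; the micro-GA
    then optimizes the per-phoneme topologies (fitness = WAcc on the
    speaker's fitness split) and the optimized recognizer is scored on
    the same test split.  Stage failures are recorded per speaker and the
    run continues.
    """
    cohort = make_cohort(
        n_speakers=config.n_speakers,
        severity_levels=(
            list(config.severity_levels) if config.severity_levels else None
        ),
        seed=seed,
        spec=config.truth,
        n_nouns=config.n_nouns,
        n_verbs=config.n_verbs,
        n_sentences=config.n_sentences,
        fractions=config.fractions,
    )
    network = compile_network(cohort.lexicon, cohort.grammar)
    codec = make_codec(cohort.inventory)
    d = config.truth.feature_dim

    rows, sig_rows = [], []
    assignments: dict[str, pd.DataFrame] = {}
    convergence: dict[str, pd.DataFrame] = {}
    for i, spk in enumerate(cohort.speakers):
        train = _scheme_train_corpus(cohort, i, config.scheme)
        fit = spk.corpus.subset("fitness")
        test = spk.corpus.subset("test")
        best_baseline = None  # (name, test_wacc, alignments)
        for name in config.baseline_systems:
            topo, n_states = BASELINE_SYSTEMS[name]
            try:
                ms = train_recognizer(
                    uniform_assignment(cohort.inventory, topo, n_states),
                    config.baseline_mixtures,
                    train,
                    d,
                    config.ga.train,
                )
                fit_wacc, _ = score_corpus(ms, fit, network)
                test_wacc, aligns = score_corpus(ms, test, network)
            except Exception as exc:  # noqa: BLE001 - keep the run going
                logger.error("speaker %s baseline %s failed: %s", spk.name, name, exc)
                rows.append(
                    {
                        "speaker": spk.name,
                        "severity": spk.severity,
                        "system": name,
                        "fitness_wacc": np.nan,
                        "test_wacc": np.nan,
                        "error": str(exc),
                    }
                )
                continue
            rows.append(
                {
                    "speaker": spk.name,
                    "severity": spk.severity,
                    "system": name,
                    "fitness_wacc": fit_wacc,
                    "test_wacc": test_wacc,
                    "error": "",
                }
            )
            if best_baseline is None or test_wacc > best_baseline[1]:
                best_baseline = (name, test_wacc, aligns)

        try:
            ga_cfg = GAConfig(
                x=config.ga.x,
                t=config.ga.t,
                seed=seed * 1009 + i,
                baseline_mixtures=config.baseline_mixtures,
                train=config.ga.train,
            )
            result = run_micro_ga(
                ga_cfg, codec, train, fit, cohort.lexicon, cohort.grammar
            )
            assign, n_mix = codec.decode(result.best.chromosome)
            ms = train_recognizer(assign, n_mix, train, d, config.ga.train)
            test_wacc, ga_aligns = score_corpus(ms, test, network)
        except Exception as exc:  # noqa: BLE001
            logger.error("speaker %s GA stage failed: %s", spk.name, exc)
            rows.append(
                {
                    "speaker": spk.name,
                    "severity": spk.severity,
                    "system": "ga_op",
                    "fitness_wacc": np.nan,
                    "test_wacc": np.nan,
                    "error": str(exc),
                }
            )
            continue
        rows.append(
            {
                "speaker": spk.name,
                "severity": spk.severity,
                "system": "ga_op",
                "fitness_wacc": result.best.fitness,
                "test_wacc": test_wacc,
                "error": "",
            }
        )
        assignments[spk.name] = result.assignment.assign(n_mixtures=n_mix)
        convergence[spk.name] = result.history
        if best_baseline is not None:
            mp = matched_pairs_test(
                best_baseline[2], ga_aligns, seed=seed * 2003 + i
            )
            sig_rows.append(
                {
                    "speaker": spk.name,
                    "baseline": best_baseline[0],
                    "baseline_test_wacc": best_baseline[1],
                    "ga_op_test_wacc": test_wacc,
                    "p_value": mp.p_value,
                    "statistic": mp.statistic,
                }
            )

    report = ExperimentReport(
        comparison=pd.DataFrame(rows),
        assignments=assignments,
        convergence=convergence,
        significance=pd.DataFrame(sig_rows),
        cohort=cohort,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.comparison.to_csv(out / "comparison.csv", index=False)
        report.significance.to_csv(out / "significance.csv", index=False)
        for name, table in report.assignments.items():
            table.to_csv(out / f"assignment_{name}.csv", index=False)
        for name, hist in report.convergence.items():
            hist.to_csv(out / f"convergence_{name}.csv", index=False)
    return report
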