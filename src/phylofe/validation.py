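"""Distributional-equivalence testing between the two simulation pipelines.

Generates matched samples of non-empty reconstructed trees from the
full-simulation-plus-pruning arm and the forward-equivalent arm, computes the
summary- and block-statistic battery, and compares each statistic's two
samples with two-sided Mann-Whitney U and two-sample Kolmogorov-Smirnov
tests.  p-values are reported raw, per statistic (no multiplicity
correction); the KS null distribution is asymptotic and only approximately
valid for discrete count statistics, so small-count KS p-values should be
read with caution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fe import simulate_reconstructed
from .fullsim import simulate_full
from .nonobs import prob_nonempty, solve_nonobservation
from .params import BDMSParams, validate_params
from .pruning import prune
from .stats import block_decomposition, summary_stats

__all__ = ["compare_distributions", "run_equivalence_suite", "collect_statistics"]

DEFAULT_RETRY_CAP = 10**6


def compare_distributions(sample_a, sample_b) -> tuple[float, float]:
    """(two-sided Mann-Whitney-U p, two-sample KS p) for two samples of a
    scalar statistic.  Samples that are jointly constant (a degenerate point
    mass in both arms) are reported as non-rejections (p = 1)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.ptp(np.concatenate([a, b])) == 0.0:
        return 1.0, 1.0
    mw = sps.mannwhitneyu(a, b, alternative="two-sided")
    ks = sps.ks_2samp(a, b)
    return float(mw.pvalue), float(ks.pvalue)


def collect_statistics(trees, cross_sections=()) -> dict[str, list[float]]:
    """Per-tree summary statistics plus pooled per-block statistics for a
    collection of non-empty reconstructed trees.

    Per-tree entries have one value per tree; ``subtree_size`` and the
    ``block_*`` entries are pooled (each tree may contribute several values,
    larger trees contributing more)."""
    out: dict[str, list[float]] = {}

    def push(key, value):
        out.setdefault(key, []).append(float(value))

    for tree in trees:
        s = summary_stats(tree, cross_sections=tuple(cross_sections))
        push("event_count", s.event_count)
        push("leaf_count", s.leaf_count)
        push("branch_length_total", s.branch_length_total)
        for lb, v in sorted(s.branch_length_by_type.items()):
            push(f"branch_length[{lb}]", v)
        for (lb, t), v in sorted(s.lineage_counts.items()):
            push(f"lineage_count[{lb}]@tau={t:g}", v)
        for size, k in s.subtree_sizes.items():
            out.setdefault("subtree_size", []).extend([float(size)] * k)
        for blk in block_decomposition(tree):
            push(f"block_events[{blk.type}]", blk.event_count)
            push(f"block_branch_length[{blk.type}]", blk.total_branch_length)
    return out


def _full_arm_nonempty(theta, rng, reps, retry_cap):
    trees, retries, exceeded = [], 0, 0
    while len(trees) < reps:
        tree, cap = simulate_full(theta, rng, validate=False)
        exceeded += cap
        if cap:
            continue
        rec = prune(tree)
        if rec.is_empty:
            retries += 1
            if retries > retry_cap:
                raise RuntimeError(
                    f"exceeded {retry_cap} empty-tree retries in the full arm; "
                    "is prob_nonempty effectively zero?"
                )
            continue
        trees.append(rec)
    return trees, retries, exceeded


def run_equivalence_suite(theta: BDMSParams, reps_per_arm: int,
                          rng: np.random.Generator,
                          cross_sections=(),
                          retry_cap: int = DEFAULT_RETRY_CAP) -> pd.DataFrame:
    """Compare full+prune against forward-equivalent simulation on ``theta``.

    Generates ``reps_per_arm`` non-empty reconstructed trees per arm (the
    full arm redraws empty replicates, up to ``retry_cap``), computes the
    statistic battery, and returns one row per statistic with both p-values
    and the two sample sizes.  Attributes ``df.attrs`` record retry and
    capacity-exceedance counts.
    """
    problems = validate_params(theta)
    if problems:
        raise ValueError("invalid BDMS parameters: " + "; ".join(problems))
    sol = solve_nonobservation(theta)
    if prob_nonempty(theta, sol) <= 0.0:
        raise ValueError("prob_nonempty(theta) = 0; the full arm cannot terminate")
    if reps_per_arm < 2:
        raise ValueError("reps_per_arm must be >= 2 for two-sample tests")

    full_trees, retries, exceeded = _full_arm_nonempty(theta, rng, reps_per_arm, retry_cap)
    fe_trees = [simulate_reconstructed(theta, rng, validate=False)
                for _ in range(reps_per_arm)]

    stats_full = collect_statistics(full_trees, cross_sections)
    stats_fe = collect_statistics(fe_trees, cross_sections)

    rows = []
    for key in sorted(set(stats_full) | set(stats_fe)):
        a = stats_full.get(key, [])
        b = stats_fe.get(key, [])
        if len(a) < 2 or len(b) < 2:
            rows.append({"statistic": key, "mw_p": np.nan, "ks_p": np.nan,
                         "n_full": len(a), "n_fe": len(b),
                         "note": "too few values for a two-sample test"})
            continue
        mw_p, ks_p = compare_distributions(a, b)
        rows.append({"statistic": key, "mw_p": mw_p, "ks_p": ks_p,
                     "n_full": len(a), "n_fe": len(b), "note": ""})
    df = pd.DataFrame(rows)
    df.attrs["full_arm_empty_retries"] = retries
    df.attrs["capacity_exceedances"] = exceeded
    df.attrs["reps_per_arm"] = reps_per_arm
    df.attrs["multiplicity_note"] = (
        "raw per-statistic p-values; apply a Bonferroni correction over "
        f"{len(rows)} statistics for familywise control"
    )
    return df
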