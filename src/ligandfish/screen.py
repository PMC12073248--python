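"""The differential screening core.

Features from replicate control and enzyme-incubated injections are matched
under ppm/RT tolerances, replicate areas are aggregated, and per-feature
one-way ANOVA p-values on log areas are corrected for multiple testing with
the Benjamini–Hochberg (BH) step-up.  A candidate binder is a matched feature
whose intensity drops significantly upon enzyme exposure.

Defaults mirror a QTOF screening workflow: 10 ppm mass tolerance, 0.3 min RT
window, screening significance 0.05, and a 1.5-fold minimum change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .feature_io import FeatureRun

__all__ = [
    "MatchedFeature",
    "BinderCall",
    "PCAResult",
    "match_runs",
    "anova_pvalues",
    "bh_adjust",
    "call_binders",
    "pca_qc",
    "binder_table",
    "write_binder_table",
]

RunKey = tuple[str, int]  # (condition, replicate)


@dataclass
class MatchedFeature:
    """One consensus feature with its per-run areas.

    ``areas`` maps (condition, replicate) to the measured area; runs in which
    the feature was not detected are simply absent from the map.
    """

    consensus_mz: float
    consensus_rt: float
    polarity: str
    areas: dict[RunKey, float] = field(default_factory=dict)

    def condition_areas(self, condition: str, run_keys: Sequence[RunKey]) -> np.ndarray:
        """Areas for one condition over the full run grid; missing -> 0."""
        return np.array([self.areas.get(k, 0.0) for k in run_keys if k[0] == condition])

    def observed_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for (condition, _rep) in self.areas:
            counts[condition] = counts.get(condition, 0) + 1
        return counts


@dataclass
class BinderCall:
    """Statistics and decision for one matched feature."""

    matched: MatchedFeature
    log2fc: float
    p_value: float
    q_value: float
    decision: str  # binder | unchanged | increased
    underpowered: bool = False


@dataclass
class PCAResult:
    scores: pd.DataFrame  # index = (condition, replicate), columns PC1..PCk
    explained_variance_ratio: np.ndarray
    condition_silhouette: Optional[float]


def _ppm_distance(a: float, b: float) -> float:
    return abs(a - b) / ((a + b) / 2.0) * 1e6


def match_runs(
    runs: Sequence[FeatureRun],
    tol_ppm: float = 10.0,
    tol_rt: float = 0.3,
) -> list[MatchedFeature]:
    """Greedy nearest-neighbour grouping of features across runs.

    Seeds are taken in descending area order; for each seed, every other run
    contributes at most its closest unused feature within both tolerances
    (ranked by ppm distance, ties broken by RT distance).  Each feature is
    used exactly once; features with no cross-run partner become
    single-condition matches.  Consensus m/z and RT are area-weighted means.
    """
    if not runs:
        return []
    polarities = {r.polarity for r in runs}
    if len(polarities) > 1:
        raise ValueError(f"mixed polarity input: {sorted(polarities)}")
    polarity = runs[0].polarity

    # Per-run sorted m/z arrays for windowed candidate lookup.
    run_mz: list[np.ndarray] = []
    run_rt: list[np.ndarray] = []
    run_area: list[np.ndarray] = []
    run_order: list[np.ndarray] = []
    used: list[np.ndarray] = []
    for run in runs:
        mz = np.array([f.mz for f in run.features])
        order = np.argsort(mz, kind="stable")
        run_order.append(order)
        run_mz.append(mz[order])
        run_rt.append(np.array([f.rt for f in run.features])[order])
        run_area.append(np.array([f.area for f in run.features])[order])
        used.append(np.zeros(mz.size, dtype=bool))

    seeds = sorted(
        ((ri, si) for ri, run in enumerate(runs) for si in range(len(run.features))),
        key=lambda idx: -runs[idx[0]].features[idx[1]].area,
    )
    # Map original feature index -> position in the sorted arrays.
    inverse = [np.argsort(order, kind="stable") for order in run_order]

    matches: list[MatchedFeature] = []
    for run_idx, feat_idx in seeds:
        pos = inverse[run_idx][feat_idx]
        if used[run_idx][pos]:
            continue
        used[run_idx][pos] = True
        seed_mz = run_mz[run_idx][pos]
        seed_rt = run_rt[run_idx][pos]
        members: list[tuple[int, int]] = [(run_idx, pos)]
        for other in range(len(runs)):
            if other == run_idx or run_mz[other].size == 0:
                continue
            half = seed_mz * tol_ppm * 1e-6
            lo = np.searchsorted(run_mz[other], seed_mz - half, side="left")
            hi = np.searchsorted(run_mz[other], seed_mz + half, side="right")
            best: Optional[tuple[float, float, int]] = None
            for cand in range(lo, hi):
                if used[other][cand]:
                    continue
                if abs(run_rt[other][cand] - seed_rt) > tol_rt:
                    continue
                d_ppm = _ppm_distance(seed_mz, run_mz[other][cand])
                if d_ppm > tol_ppm:
                    continue
                key = (d_ppm, abs(run_rt[other][cand] - seed_rt), cand)
                if best is None or key < best:
                    best = key
            if best is not None:
                cand = best[2]
                used[other][cand] = True
                members.append((other, cand))
        weights = np.array([run_area[ri][pi] for ri, pi in members])
        if weights.sum() <= 0:
            weights = np.ones(len(members))
        mzs = np.array([run_mz[ri][pi] for ri, pi in members])
        rts = np.array([run_rt[ri][pi] for ri, pi in members])
        areas = {
            (runs[ri].condition, runs[ri].replicate): float(run_area[ri][pi])
            for ri, pi in members
        }
        matches.append(
            MatchedFeature(
                consensus_mz=float(np.average(mzs, weights=weights)),
                consensus_rt=float(np.average(rts, weights=weights)),
                polarity=polarity,
                areas=areas,
            )
        )
    return matches


def _run_grid(matched: Sequence[MatchedFeature]) -> list[RunKey]:
    keys = sorted({k for m in matched for k in m.areas})
    return keys


def _pseudocount(matched: Sequence[MatchedFeature]) -> float:
    """Half the smallest nonzero area in the analysis (1.0 if none exist)."""
    smallest = np.inf
    for m in matched:
        for a in m.areas.values():
            if a > 0:
                smallest = min(smallest, a)
    return smallest / 2.0 if np.isfinite(smallest) else 1.0


def oneway_anova_p(*groups: np.ndarray) -> float:
    """One-way fixed-effects ANOVA F-test p-value (asymptotic F distribution)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    n = sum(g.size for g in groups)
    if k < 2 or n - k <= 0:
        return 1.0
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between, df_within = k - 1, n - k
    if ss_within == 0:
        return 1.0 if ss_between == 0 else 0.0
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    return float(special.fdtrc(df_between, df_within, f_stat))


def anova_pvalues(
    matched: Sequence[MatchedFeature],
    pseudocount: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature control-vs-enzyme ANOVA p-values on log areas.

    Areas are log-transformed after adding a pseudo-count (half the smallest
    nonzero area in the analysis by default).  Features with fewer than two
    detected observations in either condition get p = 1 and a raised flag —
    they are reported, not dropped.

    Returns ``(p_values, underpowered_flags)`` in input order.
    """
    if not matched:
        return np.array([]), np.array([], dtype=bool)
    keys = _run_grid(matched)
    pseudo = _pseudocount(matched) if pseudocount is None else pseudocount
    control_keys = [k for k in keys if k[0] == "control"]
    enzyme_keys = [k for k in keys if k[0] == "enzyme"]

    n_feat = len(matched)
    control = np.zeros((n_feat, len(control_keys)))
    enzyme = np.zeros((n_feat, len(enzyme_keys)))
    flags = np.zeros(n_feat, dtype=bool)
    for i, m in enumerate(matched):
        control[i] = [m.areas.get(k, 0.0) for k in control_keys]
        enzyme[i] = [m.areas.get(k, 0.0) for k in enzyme_keys]
        counts = m.observed_counts()
        if counts.get("control", 0) < 2 or counts.get("enzyme", 0) < 2:
            flags[i] = True

    log_c = np.log(control + pseudo)
    log_e = np.log(enzyme + pseudo)

    # Vectorised two-group one-way ANOVA across features.
    n1, n2 = log_c.shape[1], log_e.shape[1]
    p = np.ones(n_feat)
    if n1 >= 1 and n2 >= 1 and n1 + n2 > 2:
        m1 = log_c.mean(axis=1)
        m2 = log_e.mean(axis=1)
        grand = (n1 * m1 + n2 * m2) / (n1 + n2)
        ss_b = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
        ss_w = ((log_c - m1[:, None]) ** 2).sum(axis=1) + ((log_e - m2[:, None]) ** 2).sum(axis=1)
        df_b, df_w = 1, n1 + n2 - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat = (ss_b / df_b) / (ss_w / df_w)
        p = special.fdtrc(df_b, df_w, f_stat)
        degenerate = ss_w == 0
        p[degenerate & (ss_b == 0)] = 1.0
        p[degenerate & (ss_b > 0)] = 0.0
    p[flags] = 1.0
    return p, flags


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} (m / j) * p_(j), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * (m / np.arange(1, m + 1))
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def call_binders(
    matched: Sequence[MatchedFeature],
    alpha: float = 0.05,
    min_abs_log2fc: float = 0.585,
) -> list[BinderCall]:
    """Compute fold changes and corrected statistics, then call decisions.

    decision = "binder" iff q <= alpha and log2fc <= -min_abs_log2fc;
    "increased" for the mirrored positive case; otherwise "unchanged".
    Output is sorted by q, then |log2fc| descending.
    """
    if not matched:
        return []
    keys = _run_grid(matched)
    pseudo = _pseudocount(matched)
    p, flags = anova_pvalues(matched)
    q = bh_adjust(p)
    calls: list[BinderCall] = []
    for m, p_i, q_i, flag in zip(matched, p, q, flags):
        mean_c = float(np.mean(m.condition_areas("control", keys))) if any(k[0] == "control" for k in keys) else 0.0
        mean_e = float(np.mean(m.condition_areas("enzyme", keys))) if any(k[0] == "enzyme" for k in keys) else 0.0
        # The pseudo-count floors each condition mean, so it only acts on
        # features absent (or near-absent) on one side.
        log2fc = float(np.log2(max(mean_e, pseudo) / max(mean_c, pseudo)))
        if q_i <= alpha and log2fc <= -min_abs_log2fc:
            decision = "binder"
        elif q_i <= alpha and log2fc >= min_abs_log2fc:
            decision = "increased"
        else:
            decision = "unchanged"
        calls.append(BinderCall(m, log2fc, float(p_i), float(q_i), decision, bool(flag)))
    calls.sort(key=lambda c: (c.q_value, -abs(c.log2fc)))
    return calls


def pca_qc(matched: Sequence[MatchedFeature], n_components: int = 2) -> PCAResult:
    """PCA of the runs x features log-area matrix, plus a separation statistic.

    Areas are log2-transformed (with the analysis pseudo-count) and
    feature-centred.  The condition silhouette is computed on the first two
    score coordinates; it is None when only one condition is present.
    """
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    keys = _run_grid(matched)
    if len(keys) < 3:
        raise ValueError("PCA QC needs at least three runs")
    if n_components > len(keys):
        raise ValueError("fewer runs than requested components")
    pseudo = _pseudocount(matched)
    X = np.array([[np.log2(m.areas.get(k, 0.0) + pseudo) for m in matched] for k in keys])
    X = X - X.mean(axis=0, keepdims=True)
    pca = PCA(n_components=n_components)
    with np.errstate(invalid="ignore"):
        scores = pca.fit_transform(X)
    explained = np.nan_to_num(pca.explained_variance_ratio_)  # zero-variance input
    labels = [k[0] for k in keys]
    silhouette: Optional[float] = None
    if len(set(labels)) > 1:
        coords = scores[:, : min(2, n_components)]
        if np.allclose(coords, 0.0):
            silhouette = 0.0
        else:
            silhouette = float(silhouette_score(coords, labels))
    frame = pd.DataFrame(
        scores,
        index=pd.MultiIndex.from_tuples(keys, names=["condition", "replicate"]),
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return PCAResult(frame, explained, silhouette)


def binder_table(calls: Sequence[BinderCall]) -> pd.DataFrame:
    """Flat report: consensus m/z and RT, per-run areas, statistics, decision.

    Both the measured consensus m/z and the inferred neutral mass are
    reported, so readers need not guess which convention a column uses.
    """
    from .formula import PROTON_MASS

    keys = _run_grid(calls and [c.matched for c in calls] or [])
    rows = []
    for c in calls:
        shift = PROTON_MASS if c.matched.polarity == "negative" else -PROTON_MASS
        row = {
            "mz": c.matched.consensus_mz,
            "neutral_mass": c.matched.consensus_mz + shift,
            "rt": c.matched.consensus_rt,
            "polarity": c.matched.polarity,
            "log2fc": c.log2fc,
            "p_value": c.p_value,
            "q_value": c.q_value,
            "decision": c.decision,
            "underpowered": c.underpowered,
        }
        for condition, replicate in keys:
            row[f"area_{condition}_{replicate}"] = c.matched.areas.get((condition, replicate), np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def write_binder_table(calls: Sequence[BinderCall], path: "str | Path", delimiter: str = ",") -> None:
    binder_table(calls).to_csv(path, sep=delimiter, index=False)
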