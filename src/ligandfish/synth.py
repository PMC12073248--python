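"""Seeded generators for every input the pipeline consumes.

No public raw data exist for this kind of screen, so the test bed is
synthetic: replicate LC-MS feature runs with condition-dependent intensity
decreases for a chosen binder subset, Gaussian-peak trace fixtures for the
subtraction path, and 4PL dose–response tables for the assay reducer.

Noise model: multiplicative log-normal intensity noise (areas of LC-MS
features are multiplicative), additive Gaussian m/z error on the ppm scale,
and Gaussian RT jitter.  Defaults — 10% intensity CV, 3 ppm mass error SD,
0.05 min RT jitter — are realistic for a modern QTOF.  Every generator is a
pure function of (scenario, seed): the same seed reproduces the same bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assay import four_param_logistic
from .chromatograms import ChromatogramTrace
from .feature_io import CompoundRecord, Feature, FeatureRun, default_library
from .formula import adduct_mz, monoisotopic_mass, resolve_adduct

__all__ = [
    "RosterEntry",
    "ScreenScenario",
    "default_scenario",
    "benchmark_scenario",
    "null_scenario",
    "simulate_screen",
    "simulate_traces",
    "simulate_dose_response",
    "evaluate_calls",
]

#: Compounds reported as negative-peak features in the enzyme-incubation screen.
DEFAULT_BINDER_NAMES = frozenset(
    {
        "Gluconic acid",
        "Malic acid",
        "Citric acid",
        "Feruloyl hexose",
        "Feruloyl-glucose isomers",
        "Protocatechuoylglucose",
        "Chlorogenic acid",
        "Neochlorogenic acid",
        "(Z)-chlorogenic acid",
        "Apigenin-7-O-rhamnoglucoside (Rhoifolin)",
    }
)


@dataclass(frozen=True)
class RosterEntry:
    """One compound of the simulated extract: true m/z, RT, base area, decrease."""

    name: str
    mz: float
    rt: float
    base_area: float
    decrease: float = 0.0
    fragments: tuple[float, ...] = ()
    record: Optional[CompoundRecord] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.decrease <= 1.0):
            raise ValueError("decrease fraction must lie in [0, 1]")
        if self.base_area <= 0 or self.mz <= 0:
            raise ValueError("base area and m/z must be positive")


@dataclass(frozen=True)
class ScreenScenario:
    """Full specification of one simulated ligand-fishing experiment."""

    roster: tuple[RosterEntry, ...]
    replicates: int = 3
    cv: float = 0.10
    mz_sd_ppm: float = 3.0
    rt_jitter_sd: float = 0.05
    polarity: str = "negative"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate per condition")
        if self.cv < 0 or self.mz_sd_ppm < 0 or self.rt_jitter_sd < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def binders(self) -> tuple[RosterEntry, ...]:
        return tuple(e for e in self.roster if e.decrease > 0)


def default_scenario(
    seed: int = 0,
    decrease: float = 0.6,
    replicates: int = 3,
    cv: float = 0.10,
    mz_sd_ppm: float = 3.0,
    rt_jitter_sd: float = 0.05,
) -> ScreenScenario:
    """The packaged chamomile roster: 44 library compounds, 10 of them binders.

    Binder compounds (the ones called as negative peaks in the screen this
    emulates) decrease by ``decrease`` upon enzyme incubation; base areas are
    drawn log-uniformly over 10^4.5 to 10^6 with a seed-derived generator —
    a 1.5-decade dynamic range whose floor sits above the 1%-of-maximum
    acquisition filter, as in the exported feature lists this emulates.
    """
    rng = np.random.default_rng(seed)
    entries = []
    for record in default_library():
        spec = resolve_adduct(record.adducts[0])
        if spec.polarity != "negative":
            continue  # single-polarity screen
        entries.append(
            RosterEntry(
                name=record.name,
                mz=adduct_mz(monoisotopic_mass(record.formula), spec),
                rt=record.reference_rt if record.reference_rt is not None else 10.0,
                base_area=float(10 ** rng.uniform(4.5, 6)),
                decrease=decrease if record.name in DEFAULT_BINDER_NAMES else 0.0,
                fragments=record.diagnostic_fragments,
                record=record,
            )
        )
    return ScreenScenario(
        roster=tuple(entries),
        replicates=replicates,
        cv=cv,
        mz_sd_ppm=mz_sd_ppm,
        rt_jitter_sd=rt_jitter_sd,
        seed=seed,
    )


def _spaced_mz(rng: np.random.Generator, n: int, lo: float, hi: float, min_ppm: float) -> np.ndarray:
    """Random m/z values pairwise separated by more than min_ppm."""
    values = np.empty(0)
    while values.size < n:
        candidate = rng.uniform(lo, hi)
        if values.size == 0 or np.all(np.abs(candidate - values) / values * 1e6 > min_ppm):
            values = np.append(values, candidate)
    return values


def benchmark_scenario(
    seed: int = 0,
    n_null: int = 200,
    n_binders: int = 10,
    decrease: float = 0.6,
    replicates: int = 3,
    cv: float = 0.10,
    mz_sd_ppm: float = 3.0,
    rt_jitter_sd: float = 0.05,
) -> ScreenScenario:
    """Spike-in benchmark: ``n_binders`` true binders among ``n_null`` nulls.

    m/z values are drawn in [100, 1000] Da with > 30 ppm pairwise spacing so
    that cross-compound mismatching cannot confound the recall measurement.
    """
    rng = np.random.default_rng(seed)
    total = n_null + n_binders
    mzs = _spaced_mz(rng, total, 100.0, 1000.0, min_ppm=30.0)
    rts = rng.uniform(5.0, 33.0, size=total)
    areas = 10 ** rng.uniform(4.5, 6, size=total)
    entries = []
    for i in range(total):
        is_binder = i < n_binders
        entries.append(
            RosterEntry(
                name=f"binder_{i + 1:02d}" if is_binder else f"null_{i - n_binders + 1:03d}",
                mz=float(mzs[i]),
                rt=float(rts[i]),
                base_area=float(areas[i]),
                decrease=decrease if is_binder else 0.0,
            )
        )
    return ScreenScenario(
        roster=tuple(entries),
        replicates=replicates,
        cv=cv,
        mz_sd_ppm=mz_sd_ppm,
        rt_jitter_sd=rt_jitter_sd,
        seed=seed,
    )


def null_scenario(seed: int = 0, n_features: int = 500, **kwargs) -> ScreenScenario:
    """Pure-null scenario: no true binders at all."""
    return benchmark_scenario(seed=seed, n_null=n_features, n_binders=0, **kwargs)


def simulate_screen(scenario: ScreenScenario) -> tuple[list[FeatureRun], pd.DataFrame]:
    """Generate replicate control/enzyme runs plus the ground-truth table."""
    rng = np.random.default_rng(scenario.seed)
    sigma = float(np.sqrt(np.log1p(scenario.cv**2)))  # log-normal with unit mean
    runs: list[FeatureRun] = []
    for condition in ("control", "enzyme"):
        for replicate in range(1, scenario.replicates + 1):
            features = []
            for j, entry in enumerate(scenario.roster):
                eps_ppm = rng.normal(0.0, scenario.mz_sd_ppm)
                mz = entry.mz * (1.0 + eps_ppm * 1e-6)
                rt = max(0.0, entry.rt + rng.normal(0.0, scenario.rt_jitter_sd))
                noise = float(np.exp(rng.normal(-0.5 * sigma**2, sigma))) if sigma > 0 else 1.0
                scale = (1.0 - entry.decrease) if condition == "enzyme" else 1.0
                area = entry.base_area * scale * noise
                features.append(
                    Feature(
                        id=f"{condition[0]}{replicate}_{j}",
                        mz=float(mz),
                        rt=float(rt),
                        area=float(area),
                        height=float(area / 10.0),
                        polarity=scenario.polarity,
                        fragments=entry.fragments,
                    )
                )
            runs.append(FeatureRun("synthetic", condition, replicate, scenario.polarity, features))
    truth = pd.DataFrame(
        {
            "name": [e.name for e in scenario.roster],
            "mz": [e.mz for e in scenario.roster],
            "rt": [e.rt for e in scenario.roster],
            "base_area": [e.base_area for e in scenario.roster],
            "decrease": [e.decrease for e in scenario.roster],
            "is_binder": [e.decrease > 0 for e in scenario.roster],
        }
    )
    return runs, truth


def simulate_traces(
    scenario: ScreenScenario,
    peak_sigma: float = 0.05,
    dt: float = 0.005,
    pad: float = 1.0,
) -> tuple[ChromatogramTrace, ChromatogramTrace]:
    """Control and enzyme total traces built from Gaussian peaks.

    Each roster compound contributes a Gaussian at its true RT with amplitude
    equal to its base area (scaled by 1 − decrease in the enzyme trace); no
    noise is added — these fixtures exercise the subtraction arithmetic, not
    the detector model.
    """
    rts = np.array([e.rt for e in scenario.roster])
    grid = np.arange(rts.min() - pad, rts.max() + pad + dt, dt)
    control = np.zeros_like(grid)
    enzyme = np.zeros_like(grid)
    for entry in scenario.roster:
        shape = np.exp(-0.5 * ((grid - entry.rt) / peak_sigma) ** 2)
        control += entry.base_area * shape
        enzyme += entry.base_area * (1.0 - entry.decrease) * shape
    return (
        ChromatogramTrace(grid, control, kind="TIC"),
        ChromatogramTrace(grid.copy(), enzyme, kind="TIC"),
    )


def simulate_dose_response(
    ic50: float,
    hill: float = 1.0,
    noise_sd: float = 0.0,
    doses: Optional[Sequence[float]] = None,
    seed: int = 0,
    bottom: float = 0.0,
    top: float = 100.0,
) -> pd.DataFrame:
    """4PL evaluations plus Gaussian noise, clamped at zero.

    Returns a table with ``concentration`` (µM) and ``inhibition`` (%).  The
    default dose ladder is 8 three-fold dilutions spanning the transition.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if doses is None:
        doses = ic50 * 3.0 ** np.arange(-4, 4)
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(seed)
    inhibition = four_param_logistic(doses, bottom, top, ic50, hill)
    if noise_sd > 0:
        inhibition = inhibition + rng.normal(0.0, noise_sd, size=doses.shape)
    inhibition = np.maximum(inhibition, 0.0)
    return pd.DataFrame({"concentration": doses, "inhibition": inhibition})


def evaluate_calls(
    calls,
    truth: pd.DataFrame,
    tol_ppm: float = 10.0,
    tol_rt: float = 0.3,
) -> dict:
    """Recall and empirical FDR of binder calls against the ground truth.

    A call counts as a true positive when its consensus (m/z, RT) lies within
    tolerance of a spiked binder; each true binder is credited once.
    """
    binder_truth = truth[truth["is_binder"]]
    called = [c for c in calls if c.decision == "binder"]
    credited: set[int] = set()
    tp = fp = 0
    for call in called:
        hit = None
        for row in binder_truth.itertuples():
            if row.Index in credited:
                continue
            d_ppm = abs(call.matched.consensus_mz - row.mz) / row.mz * 1e6
            if d_ppm <= tol_ppm and abs(call.matched.consensus_rt - row.rt) <= tol_rt:
                hit = row.Index
                break
        if hit is None:
            fp += 1
        else:
            credited.add(hit)
            tp += 1
    n_true = int(binder_truth.shape[0])
    recall = tp / n_true if n_true else float("nan")
    fdr = fp / max(tp + fp, 1)
    return {"tp": tp, "fp": fp, "fn": n_true - tp, "recall": recall, "fdr": fdr, "n_called": len(called)}
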