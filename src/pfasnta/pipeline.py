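"""Feature alignment and the PFAS prioritization cascade.

Implements the non-target screening filter chain applied to case/control
feature tables: replicate-RSD filter, procedural-blank ratio filter,
retention-time window, CF2 Kendrick-mass-defect window, and case-control
fold-change/Welch-t selection. Filters are independent predicates; the
cascade survivor set equals the intersection of the individual pass sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .chem import KendrickValues, kendrick

__all__ = [
    "FeatureObservation",
    "AlignedFeature",
    "CaseControlStats",
    "PipelineConfig",
    "StudyDesign",
    "align_observations",
    "replicate_rsd_filter",
    "blank_filter",
    "rt_window_filter",
    "kmd_window_filter",
    "case_control_stats",
    "welch_ttest",
    "prioritize",
]

CASE, CONTROL, BLANK, SOLVENT_BLANK = "case", "control", "blank", "solvent_blank"
VALID_GROUPS = frozenset({CASE, CONTROL, BLANK, SOLVENT_BLANK})


@dataclass(frozen=True)
class FeatureObservation:
    """One detected MS1 peak in one injection."""

    mz: float
    rt: float  #: retention time, minutes
    intensity: float  #: peak height, cps scale
    sample_id: str  #: pooled-sample label (e.g. "case1")
    replicate: int  #: injection number within the sample, 1-based
    group: str  #: case / control / blank / solvent_blank
    feature_id: str | None = None  #: optional source label (carried to truth)

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"mz must be positive, got {self.mz}")
        if self.rt < 0 or self.intensity < 0:
            raise ValueError("rt and intensity must be non-negative")
        if self.group not in VALID_GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")

    @property
    def run_id(self) -> str:
        """Unique injection key."""
        return f"{self.sample_id}:{self.replicate}"


@dataclass
class CaseControlStats:
    """Welch t-test on log2 pool-mean intensities, case vs control."""

    log_fold_change: float
    p_value: float
    case_mean: float
    control_mean: float


@dataclass
class AlignedFeature:
    """A consensus m/z x RT feature with per-injection intensities."""

    feature_id: str
    mz: float  #: intensity-weighted consensus m/z
    rt: float  #: intensity-weighted consensus RT (min)
    intensities: dict[str, float]  #: run_id -> intensity (0 = not detected)
    kendrick: KendrickValues | None = None
    ms2: object | None = None  #: optional spectra attached downstream
    filter_flags: dict[str, bool] = field(default_factory=dict)
    stats: CaseControlStats | None = None
    source_ids: dict[str, int] = field(default_factory=dict)  #: input feature_id -> member count

    def intensity(self, run_id: str) -> float:
        return self.intensities.get(run_id, 0.0)

    @property
    def source_id(self) -> str | None:
        """Modal input feature label among members, if inputs carried one."""
        if not self.source_ids:
            return None
        return max(sorted(self.source_ids), key=lambda k: self.source_ids[k])


@dataclass(frozen=True)
class PipelineConfig:
    """Tolerances and thresholds of the prioritization cascade.

    Defaults encode the screening conditions: 0.02 Da XIC width, 30 s RT
    tolerance, 5000 cps minimum height, triplicate RSD < 20%, blank ratio
    > 10x, RT 1-13 min, KMD in [-0.15, 0.15], log2 fold change > 0.9 with
    p < 0.05 (raw, no multiple-testing correction by default).
    """

    mz_tol: float = 0.02  #: Da
    rt_tol: float = 30.0  #: seconds
    min_intensity: float = 5000.0  #: cps, applied at observation ingestion
    rsd_max: float = 20.0  #: percent, strict <
    blank_factor: float = 10.0  #: strict >
    rt_window: tuple[float, float] = (1.0, 13.0)  #: minutes, inclusive
    kmd_window: tuple[float, float] = (-0.15, 0.15)  #: Da, inclusive
    lfc_min: float = 0.9  #: strict >
    p_max: float = 0.05  #: strict <
    imputation_floor: float = 0.5  #: fraction of smallest positive intensity
    log_base: float = 2.0
    bh_correction: bool = False  #: Benjamini-Hochberg across features, off by default

    def __post_init__(self) -> None:
        if self.mz_tol <= 0 or self.rt_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.rt_window[0] > self.rt_window[1] or self.kmd_window[0] > self.kmd_window[1]:
            raise ValueError("windows must be ordered (low, high)")

    @property
    def rt_tol_min(self) -> float:
        return self.rt_tol / 60.0


class StudyDesign:
    """Maps injections to groups and pooled samples.

    Built from the observation table; ``groups[group][sample_id]`` is the
    tuple of run_ids (injections) of that pooled sample.
    """

    def __init__(self, groups: Mapping[str, Mapping[str, Sequence[str]]]):
        self.groups = {
            g: {s: tuple(runs) for s, runs in sorted(samples.items())}
            for g, samples in groups.items()
        }

    @classmethod
    def from_observations(cls, obs: Iterable[FeatureObservation]) -> "StudyDesign":
        groups: dict[str, dict[str, set[str]]] = {}
        for o in obs:
            groups.setdefault(o.group, {}).setdefault(o.sample_id, set()).add(o.run_id)
        return cls({g: {s: tuple(sorted(r)) for s, r in ss.items()} for g, ss in groups.items()})

    def samples(self, group: str) -> dict[str, tuple[str, ...]]:
        return self.groups.get(group, {})

    def runs(self, group: str) -> list[str]:
        return [r for runs in self.samples(group).values() for r in runs]

    def require(self, *groups: str) -> None:
        missing = [g for g in groups if not self.groups.get(g)]
        if missing:
            raise ValueError(f"study design missing groups: {missing}")


def align_observations(
    obs: Sequence[FeatureObservation], cfg: PipelineConfig
) -> list[AlignedFeature]:
    """Greedy intensity-seeded clustering of observations into features.

    Observations are visited in order of descending intensity (m/z
    tie-break); each unassigned observation seeds a feature and absorbs
    every unassigned observation within ``mz_tol`` and ``rt_tol`` of the
    seed. Per-injection intensity is the max over member observations;
    consensus m/z and RT are intensity-weighted means. Deterministic and
    input-order independent.
    """
    obs = [o for o in obs if o.intensity >= cfg.min_intensity or o.group in (BLANK, SOLVENT_BLANK)]
    if not obs:
        return []
    mzs = np.array([o.mz for o in obs])
    rts = np.array([o.rt for o in obs])
    ints = np.array([o.intensity for o in obs])
    # total order: intensity desc, then m/z, rt, run_id for determinism
    visit = sorted(
        range(len(obs)), key=lambda i: (-ints[i], mzs[i], rts[i], obs[i].run_id)
    )
    mz_order = np.argsort(mzs, kind="stable")
    mz_sorted = mzs[mz_order]
    assigned = np.zeros(len(obs), dtype=bool)
    rt_tol = cfg.rt_tol_min
    features: list[AlignedFeature] = []
    for seed in visit:
        if assigned[seed]:
            continue
        lo = np.searchsorted(mz_sorted, mzs[seed] - cfg.mz_tol, side="left")
        hi = np.searchsorted(mz_sorted, mzs[seed] + cfg.mz_tol, side="right")
        cand = mz_order[lo:hi]
        cand = cand[~assigned[cand]]
        cand = cand[np.abs(rts[cand] - rts[seed]) <= rt_tol]
        assigned[cand] = True
        members = [obs[i] for i in cand]
        w = ints[cand]
        if w.sum() <= 0:
            w = np.ones_like(w)
        cons_mz = float(np.average(mzs[cand], weights=w))
        cons_rt = float(np.average(rts[cand], weights=w))
        intensities: dict[str, float] = {}
        sources: dict[str, int] = {}
        for m in members:
            intensities[m.run_id] = max(intensities.get(m.run_id, 0.0), m.intensity)
            if m.feature_id is not None:
                sources[m.feature_id] = sources.get(m.feature_id, 0) + 1
        features.append(
            AlignedFeature(
                feature_id="",
                mz=cons_mz,
                rt=cons_rt,
                intensities=intensities,
                kendrick=kendrick(cons_mz),
                source_ids=sources,
            )
        )
    features.sort(key=lambda f: (f.mz, f.rt))
    for i, f in enumerate(features, start=1):
        f.feature_id = f"F{i:05d}"
    return features


def _rsd_percent(values: np.ndarray) -> float:
    m = values.mean()
    if m == 0:
        return math.inf
    return float(values.std(ddof=1) / m * 100.0)


def replicate_rsd_filter(
    feat: AlignedFeature, replicate_runs: Sequence[str], cfg: PipelineConfig
) -> bool:
    """True iff the feature is present in every replicate injection and the
    replicate RSD (sample sd / mean x 100, raw intensities) is < rsd_max."""
    if len(replicate_runs) < 2:
        raise ValueError("RSD undefined for fewer than 2 replicates")
    vals = np.array([feat.intensity(r) for r in replicate_runs])
    if np.any(vals <= 0):
        return False
    return _rsd_percent(vals) < cfg.rsd_max


def _case_detection_rsd(feat: AlignedFeature, design: StudyDesign, cfg: PipelineConfig) -> bool:
    """Feature passes if >=1 case pool detects it in all injections with RSD < max."""
    ok = False
    for runs in design.samples(CASE).values():
        if len(runs) < 2:
            raise ValueError("RSD undefined for fewer than 2 replicates")
        vals = np.array([feat.intensity(r) for r in runs])
        if np.all(vals > 0) and _rsd_percent(vals) < cfg.rsd_max:
            ok = True
    return ok


def _case_mean(feat: AlignedFeature, design: StudyDesign) -> float:
    runs = design.runs(CASE)
    if not runs:
        return 0.0
    return float(np.mean([feat.intensity(r) for r in runs]))


def blank_filter(
    feat: AlignedFeature, blank_runs: Sequence[str], cfg: PipelineConfig, case_mean: float | None = None
) -> bool:
    """True iff mean case intensity exceeds blank_factor x the maximum
    procedural-blank intensity (strict >). Blank-absent features pass
    whenever the case mean is positive."""
    if case_mean is None:
        raise ValueError("case_mean required")
    blank_max = max((feat.intensity(r) for r in blank_runs), default=0.0)
    if blank_max == 0.0:
        return case_mean > 0.0
    return case_mean > cfg.blank_factor * blank_max


def rt_window_filter(feat: AlignedFeature, cfg: PipelineConfig) -> bool:
    lo, hi = cfg.rt_window
    return lo <= feat.rt <= hi


def kmd_window_filter(feat: AlignedFeature, cfg: PipelineConfig) -> bool:
    if feat.kendrick is None:
        raise ValueError("kendrick values not computed")
    lo, hi = cfg.kmd_window
    return lo <= feat.kendrick.kmd <= hi


def welch_ttest(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch unequal-variance t-test, Welch-Satterthwaite df.

    Returns (t, p). Degenerate case of zero variance in both groups:
    p = 1 when the means are equal, else p = 0.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >=2 values per group")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        return (0.0, 1.0) if diff == 0 else (math.inf, 0.0)
    t = diff / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def case_control_stats(
    feat: AlignedFeature,
    design: StudyDesign,
    cfg: PipelineConfig,
    floor: float | None = None,
) -> CaseControlStats:
    """Fold change and Welch p-value on log-transformed pool means.

    Per-pool intensity is the mean over that pool's injections. Zeros are
    imputed as ``imputation_floor x floor_reference`` where the reference is
    the smallest positive intensity in the aligned table (passed as
    ``floor``) or, standalone, in this feature. The test is Welch's
    unequal-variance t on log2 values, two-sided.
    """
    case_pools = [
        float(np.mean([feat.intensity(r) for r in runs]))
        for runs in design.samples(CASE).values()
    ]
    ctrl_pools = [
        float(np.mean([feat.intensity(r) for r in runs]))
        for runs in design.samples(CONTROL).values()
    ]
    if len(case_pools) < 2 or len(ctrl_pools) < 2:
        raise ValueError("need >=2 case and >=2 control pools")
    if floor is None:
        pos = [v for v in case_pools + ctrl_pools if v > 0]
        floor = min(pos) if pos else 1.0
    eps = cfg.imputation_floor * floor
    case = np.maximum(case_pools, eps)
    ctrl = np.maximum(ctrl_pools, eps)
    logb = math.log(cfg.log_base)
    lx, ly = np.log(case) / logb, np.log(ctrl) / logb
    _, p = welch_ttest(lx, ly)
    return CaseControlStats(
        log_fold_change=float(lx.mean() - ly.mean()),
        p_value=p,
        case_mean=float(np.mean(case_pools)),
        control_mean=float(np.mean(ctrl_pools)),
    )


FILTER_ORDER = ("rsd", "blank", "rt", "kmd", "case_control")


def table_floor(features: Sequence[AlignedFeature]) -> float:
    pos = [v for f in features for v in f.intensities.values() if v > 0]
    return min(pos) if pos else 1.0


def prioritize(
    features: Sequence[AlignedFeature],
    design: StudyDesign,
    cfg: PipelineConfig,
) -> list[AlignedFeature]:
    """Run the full cascade; return survivors with per-filter provenance.

    Every feature (surviving or not) receives ``filter_flags`` for all five
    filters and case/control statistics, so the survivor set is exactly the
    conjunction of the individual predicates.
    """
    design.require(CASE, CONTROL)
    blank_runs = design.runs(BLANK) + design.runs(SOLVENT_BLANK)
    floor = table_floor(features)
    pvals: list[float] = []
    for f in features:
        cm = _case_mean(f, design)
        f.filter_flags["rsd"] = _case_detection_rsd(f, design, cfg)
        f.filter_flags["blank"] = blank_filter(f, blank_runs, cfg, case_mean=cm)
        f.filter_flags["rt"] = rt_window_filter(f, cfg)
        f.filter_flags["kmd"] = kmd_window_filter(f, cfg)
        f.stats = case_control_stats(f, design, cfg, floor=floor)
        pvals.append(f.stats.p_value)
    if cfg.bh_correction and features:
        adj = _bh_adjust(np.array(pvals))
        for f, q in zip(features, adj):
            f.stats.p_value = float(q)
    for f in features:
        f.filter_flags["case_control"] = (
            f.stats.log_fold_change > cfg.lfc_min and f.stats.p_value < cfg.p_max
        )
    return [f for f in features if all(f.filter_flags[name] for name in FILTER_ORDER)]


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
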