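"""Homologous-series detection in (m/z, KMD, RT) space.

Members of a perfluoroalkyl homologous series differ by integer numbers of
a repeat unit (CF2 by default) and share a Kendrick mass defect, so they
appear horizontally adjacent in a KMD vs m/z plot. Detection builds a graph
whose edges are unit-spaced feature pairs passing both an m/z and a KMD
tolerance, takes connected components, prunes them to KMD coherence, and
reports maximal series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem import Formula, monoisotopic_mass, parse_formula
from .pipeline import AlignedFeature

__all__ = ["HomologueSeries", "detect_series", "series_rt_consistency", "REPEAT_UNITS"]

#: Repeat units offered out of the box; CF2 is the PFAS default.
REPEAT_UNITS = {
    "CF2": parse_formula("CF2"),
    "C2F4": parse_formula("C2F4"),
    "CH2": parse_formula("CH2"),
    "C2H4O": parse_formula("C2H4O"),
}


@dataclass
class HomologueSeries:
    """An ordered CF2 (or other unit) homologous series."""

    series_id: str
    unit: Formula
    members: list[str]  #: feature_ids, ascending m/z
    member_mz: list[float]
    member_kmd: list[float]
    unit_counts: list[int]  #: unit spacing between consecutive members
    mean_kmd: float

    def __len__(self) -> int:
        return len(self.members)


def _prune_kmd(idx: list[int], kmds: np.ndarray, kmd_tol: float) -> list[int]:
    """Iteratively drop the member farthest from the mean KMD until all
    members sit within kmd_tol of the group mean."""
    idx = list(idx)
    while len(idx) >= 2:
        sub = kmds[idx]
        dev = np.abs(sub - sub.mean())
        if dev.max() <= kmd_tol:
            break
        idx.pop(int(dev.argmax()))
    return idx


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def detect_series(
    features: Sequence[AlignedFeature],
    unit: Formula | str = "CF2",
    kmd_tol: float = 0.005,
    mz_tol: float = 0.01,
    min_members: int = 2,
    max_unit_steps: int = 12,
) -> list[HomologueSeries]:
    """Group features into homologous series of the given repeat unit.

    An edge links features i < j (by m/z) when the m/z difference is within
    ``mz_tol * k`` of ``k`` unit masses for some integer 1 <= k <=
    ``max_unit_steps`` and their KMDs differ by at most ``kmd_tol``.
    Connected components are pruned so that every member KMD lies within
    ``kmd_tol`` of the component mean, then reported if they keep at least
    ``min_members`` members. Output ordering: mean KMD, then lowest m/z.
    Deterministic and independent of input order.
    """
    if min_members < 2:
        raise ValueError("min_members must be >= 2")
    if isinstance(unit, str):
        unit = REPEAT_UNITS.get(unit) or parse_formula(unit)
    unit_mass = monoisotopic_mass(unit)
    feats = sorted(features, key=lambda f: (f.mz, f.feature_id))
    n = len(feats)
    if n == 0:
        return []
    for f in feats:
        if f.kendrick is None:
            raise ValueError(f"feature {f.feature_id} lacks Kendrick values")
    mzs = np.array([f.mz for f in feats])
    kmds = np.array([f.kendrick.kmd for f in feats])
    uf = _UnionFind(n)
    for i in range(n):
        lo = np.searchsorted(mzs, mzs[i] + unit_mass - mz_tol * 1)
        hi = np.searchsorted(
            mzs, mzs[i] + max_unit_steps * unit_mass + mz_tol * max_unit_steps, side="right"
        )
        for j in range(int(lo), int(hi)):
            d = mzs[j] - mzs[i]
            k = int(round(d / unit_mass))
            if k < 1 or k > max_unit_steps:
                continue
            if abs(d - k * unit_mass) <= mz_tol * k and abs(kmds[j] - kmds[i]) <= kmd_tol:
                uf.union(i, j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(uf.find(i), []).append(i)
    series: list[HomologueSeries] = []
    for idx in comps.values():
        idx = _prune_kmd(sorted(idx), kmds, kmd_tol)
        if len(idx) < min_members:
            continue
        mz_m = [float(mzs[i]) for i in idx]
        spacing = [int(round((b - a) / unit_mass)) for a, b in zip(mz_m, mz_m[1:])]
        if any(k < 1 for k in spacing):
            continue
        series.append(
            HomologueSeries(
                series_id="",
                unit=unit,
                members=[feats[i].feature_id for i in idx],
                member_mz=mz_m,
                member_kmd=[float(kmds[i]) for i in idx],
                unit_counts=spacing,
                mean_kmd=float(np.mean([kmds[i] for i in idx])),
            )
        )
    series.sort(key=lambda s: (s.mean_kmd, s.member_mz[0]))
    for i, s in enumerate(series, start=1):
        s.series_id = f"S{i:03d}"
    return series


def series_rt_consistency(
    series: HomologueSeries,
    features: Sequence[AlignedFeature],
    slack: float = 0.0,
) -> bool:
    """Check that retention time increases with m/z along the series.

    Reversed-phase convention: longer perfluoroalkyl chains elute later.
    With ``slack`` (minutes per repeat unit) the requirement for each
    consecutive pair k units apart is rt[j] - rt[i] > -slack * k; slack 0
    demands strictly increasing RT.
    """
    by_id = {f.feature_id: f for f in features}
    rts = []
    for fid in series.members:
        f = by_id.get(fid)
        if f is None or f.rt is None:
            raise ValueError(f"missing RT for series member {fid}")
        rts.append(f.rt)
    for (a, b), k in zip(zip(rts, rts[1:]), series.unit_counts):
        if not (b - a > -slack * k):
            return False
    return True
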