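"""Readers/writers for the plain-text formats the pipeline exchanges.

Feature observations and reports travel as CSV (pandas); MS/MS spectra as
MGF (pyteomics), with TITLE lines of the form ``<feature_id>|rep<k>``
linking replicate spectra to features; suspect lists and spectral
libraries as CSV.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from pyteomics import mgf as _mgf

from .annotate import LibraryEntry, Spectrum, SuspectEntry
from .chem import parse_formula
from .homologue import HomologueSeries
from .pipeline import AlignedFeature, FeatureObservation, PipelineConfig

__all__ = [
    "SchemaError",
    "read_feature_observations",
    "write_feature_observations",
    "read_spectra",
    "write_spectra",
    "read_suspects",
    "read_library",
    "write_survivor_report",
    "write_series_report",
    "write_kmd_plot_data",
    "RunConfig",
]

OBSERVATION_COLUMNS = ("mz", "rt_min", "intensity", "sample_id", "replicate", "group")


class SchemaError(ValueError):
    """Raised when an input file violates the expected schema."""


def read_feature_observations(path: str | Path) -> list[FeatureObservation]:
    """Read an observation CSV (columns mz, rt_min, intensity, sample_id,
    replicate, group; optional feature_id). Malformed rows raise with their
    1-based data line number."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    has_fid = "feature_id" in df.columns
    out: list[FeatureObservation] = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            out.append(
                FeatureObservation(
                    mz=float(d["mz"]),
                    rt=float(d["rt_min"]),
                    intensity=float(d["intensity"]),
                    sample_id=str(d["sample_id"]),
                    replicate=int(d["replicate"]),
                    group=str(d["group"]),
                    feature_id=(str(d["feature_id"]) if has_fid and pd.notna(d["feature_id"]) else None),
                )
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: bad row at line {line}: {exc}") from exc
    return out


def write_feature_observations(obs: Iterable[FeatureObservation], path: str | Path) -> None:
    rows = [
        dict(
            feature_id=o.feature_id or "", mz=o.mz, rt_min=o.rt, intensity=o.intensity,
            sample_id=o.sample_id, replicate=o.replicate, group=o.group,
        )
        for o in obs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _check_mgf_balance(path: Path) -> None:
    begins = ends = 0
    block = 0
    for raw in path.read_text().splitlines():
        line = raw.strip().upper()
        if line == "BEGIN IONS":
            block += 1
            begins += 1
            if begins != ends + 1:
                raise SchemaError(f"{path}: nested BEGIN IONS at block {block}")
        elif line == "END IONS":
            ends += 1
            if ends > begins:
                raise SchemaError(f"{path}: unmatched END IONS at block {block}")
    if begins != ends:
        raise SchemaError(f"{path}: BEGIN/END IONS imbalance at block {begins}")


def read_spectra(path: str | Path) -> dict[str, list[Spectrum]]:
    """Read an MGF file into feature_id -> replicate spectra.

    TITLE must be ``<feature_id>`` or ``<feature_id>|rep<k>``; peaks are
    sorted on read. An empty file yields an empty map.
    """
    path = Path(path)
    _check_mgf_balance(path)
    out: dict[str, list[Spectrum]] = {}
    if path.stat().st_size == 0:
        return out
    with _mgf.read(str(path), use_index=False) as reader:
        for block in reader:
            title = str(block["params"].get("title", "")).strip()
            fid = title.split("|")[0] if title else ""
            if not fid:
                raise SchemaError(f"{path}: spectrum block without TITLE")
            pep = block["params"].get("pepmass", (0.0,))[0] or 0.0
            peaks = list(zip(block["m/z array"], block["intensity array"]))
            if not peaks:
                continue
            out.setdefault(fid, []).append(Spectrum(precursor_mz=float(pep), peaks=peaks))
    return out


def write_spectra(spectra: Mapping[str, Sequence[Spectrum]], path: str | Path) -> None:
    blocks = []
    for fid in sorted(spectra):
        for k, s in enumerate(spectra[fid], start=1):
            blocks.append(
                {
                    "m/z array": s.mz,
                    "intensity array": s.intensity,
                    "params": {"title": f"{fid}|rep{k}", "pepmass": s.precursor_mz, "charge": "1-"},
                }
            )
    with open(path, "w") as fh:
        _mgf.write(blocks, fh)


def read_suspects(path: str | Path) -> list[SuspectEntry]:
    """Suspect CSV: name, formula, ion_mode, class, source."""
    df = pd.read_csv(path, dtype=str).fillna("")
    for col in ("name", "formula"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    out = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            out.append(
                SuspectEntry(
                    name=d["name"],
                    formula=parse_formula(d["formula"]),
                    ion_mode=d.get("ion_mode") or "deprotonated",
                    class_label=d.get("class", "") or d.get("class_label", ""),
                    source=d.get("source", ""),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: bad suspect at line {line}: {exc}") from exc
    return out


def read_library(path: str | Path) -> list[LibraryEntry]:
    """Spectral-library CSV: name, formula, ion_mode, class, precursor_mz,
    peaks (semicolon-separated ``mz:intensity`` pairs)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    for col in ("name", "formula", "peaks"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    out = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            peaks = []
            for tok in d["peaks"].split(";"):
                tok = tok.strip()
                if tok:
                    mz_s, int_s = tok.split(":")
                    peaks.append((float(mz_s), float(int_s)))
            formula = parse_formula(d["formula"])
            ion_mode = d.get("ion_mode") or ("ion" if formula.charge else "deprotonated")
            prec = float(d["precursor_mz"]) if d.get("precursor_mz") else 0.0
            spec = Spectrum(precursor_mz=prec, peaks=peaks)
            out.append(
                LibraryEntry(
                    name=d["name"], formula=formula, ion_mode=ion_mode,
                    spectrum=spec, class_label=d.get("class", ""),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: bad library entry at line {line}: {exc}") from exc
    return out


def write_survivor_report(features: Sequence[AlignedFeature], path: str | Path) -> None:
    """Survivor/flag CSV: one row per feature with filter provenance."""
    rows = []
    for f in features:
        row = dict(
            feature_id=f.feature_id,
            source_id=f.source_id or "",
            mz=round(f.mz, 6),
            rt_min=round(f.rt, 3),
            kmd=round(f.kendrick.kmd, 5) if f.kendrick else "",
        )
        for name, ok in f.filter_flags.items():
            row[f"pass_{name}"] = ok
        if f.stats is not None:
            row["log2fc"] = round(f.stats.log_fold_change, 4)
            row["p_value"] = f.stats.p_value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_series_report(series: Sequence[HomologueSeries], path: str | Path) -> None:
    rows = [
        dict(
            series_id=s.series_id,
            unit=str(s.unit),
            n_members=len(s),
            members=";".join(s.members),
            member_mz=";".join(f"{m:.4f}" for m in s.member_mz),
            member_kmd=";".join(f"{k:.5f}" for k in s.member_kmd),
            unit_counts=";".join(str(k) for k in s.unit_counts),
            mean_kmd=round(s.mean_kmd, 5),
        )
        for s in series
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_kmd_plot_data(
    features: Sequence[AlignedFeature],
    series: Sequence[HomologueSeries],
    path: str | Path,
) -> None:
    """m/z vs KMD table with series labels, for external KMD plotting."""
    label = {}
    for s in series:
        for fid in s.members:
            label[fid] = s.series_id
    rows = [
        dict(
            feature_id=f.feature_id, mz=round(f.mz, 6),
            kmd=round(f.kendrick.kmd, 5) if f.kendrick else "",
            series=label.get(f.feature_id, ""),
        )
        for f in features
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Serializable configuration of one workflow run."""

    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    seed: int = 42
    features_csv: str = ""
    spectra_mgf: str = ""
    suspects_csv: str = ""
    library_csv: str = ""
    out_dir: str = "results"
    kmd_tol: float = 0.005
    homologue_mz_tol: float = 0.01
    min_series_members: int = 2
    frag_tol: float = 0.01

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        pipe = d.pop("pipeline", {})
        if isinstance(pipe.get("rt_window"), list):
            pipe["rt_window"] = tuple(pipe["rt_window"])
        if isinstance(pipe.get("kmd_window"), list):
            pipe["kmd_window"] = tuple(pipe["kmd_window"])
        return cls(pipeline=PipelineConfig(**pipe), **d)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def write_provenance(path: str | Path, config: RunConfig, stage_counts: Mapping[str, int]) -> None:
    """Machine-readable provenance: config hash, seed, per-stage counts."""
    Path(path).write_text(
        json.dumps(
            dict(config_hash=config.digest(), seed=config.seed, stage_counts=dict(stage_counts)),
            indent=2,
        )
        + "\n"
    )
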