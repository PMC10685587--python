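"""TSV readers/writers and YAML run configuration.

All tables are tab-separated with '#'-prefixed metadata header lines so
they stay diff-able and language-neutral.  Floats are written with repr
precision, so write→read round-trips are bit-exact.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    DensityProfileSet,
    DiffractionCondition,
    LamellarDataset,
    NSLDProfile,
    PeakRecord,
    RunConfig,
)

log = logging.getLogger(__name__)

PEAK_COLUMNS = ["order", "two_theta", "intensity", "intensity_err", "phase_label"]


class TableFormatError(ValueError):
    """A table file does not match the expected schema."""


def _write_tsv(df: pd.DataFrame, path, metadata: dict) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in metadata.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=None)


def _read_tsv(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    metadata = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, value = stripped.partition(":")
                metadata[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    df = pd.read_csv(
        io.StringIO("".join(lines[body_start:])), sep="\t",
        float_precision="round_trip",
    )
    return df, metadata


def read_peak_table(path, condition: DiffractionCondition) -> list[LamellarDataset]:
    """Read a Bragg-peak TSV into one dataset per lamellar phase.

    Rows with non-positive intensity are rejected with a logged warning;
    a missing column or a duplicate (phase, order) pair is an error.
    """
    df, _ = _read_tsv(path)
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"peak table {path} is missing column(s): {missing}")

    n_rejected = int((df["intensity"] <= 0).sum())
    if n_rejected:
        log.warning(
            "rejected %d row(s) with non-positive intensity in %s", n_rejected, path
        )
        df = df[df["intensity"] > 0]

    dup = df.duplicated(subset=["phase_label", "order"])
    if dup.any():
        pairs = df.loc[dup, ["phase_label", "order"]].to_records(index=False)
        raise ValueError(f"duplicate (phase, order) pairs in {path}: {list(pairs)}")

    datasets = []
    for phase, group in df.groupby("phase_label", sort=True):
        peaks = [
            PeakRecord(
                order=int(row.order),
                two_theta=float(row.two_theta),
                intensity=float(row.intensity),
                intensity_err=(
                    float(row.intensity_err) if np.isfinite(row.intensity_err) else None
                ),
                phase_label=str(phase),
            )
            for row in group.itertuples()
        ]
        datasets.append(
            LamellarDataset(condition=condition, peaks=peaks, phase_label=str(phase))
        )
    log.info("read %d dataset(s), %d peak(s) from %s", len(datasets), len(df), path)
    return datasets


def write_peak_table(datasets: list[LamellarDataset], path, metadata=None) -> None:
    rows = []
    for ds in datasets:
        for p in ds.peaks:
            rows.append(
                dict(
                    order=p.order,
                    two_theta=p.two_theta,
                    intensity=p.intensity,
                    intensity_err=p.intensity_err if p.intensity_err is not None else np.nan,
                    phase_label=p.phase_label,
                )
            )
    df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    meta = {"format": "lamella peak table", "units": "two_theta:deg intensity:counts"}
    meta.update(metadata or {})
    _write_tsv(df, path, meta)


ProfileLike = Union[NSLDProfile, DensityProfileSet]


def write_profile_table(profile: ProfileLike, path) -> None:
    """Write an NSLD or density profile as TSV (z_angstrom + value columns)."""
    if isinstance(profile, NSLDProfile):
        if len(profile.z) == 0:
            raise ValueError("refusing to write an empty profile")
        bad = np.flatnonzero(~np.isfinite(profile.rho))
        if len(bad):
            raise ValueError(f"profile contains non-finite value at index {bad[0]}")
        df = pd.DataFrame({"z_angstrom": profile.z, "rho_rel": profile.rho})
        meta = {
            "format": "lamella nsld profile",
            "d_angstrom": repr(profile.d),
            "n_orders_used": profile.n_orders_used,
        }
        if profile.signs_used is not None:
            meta["signs"] = ",".join(str(int(s)) for s in profile.signs_used)
    elif isinstance(profile, DensityProfileSet):
        if len(profile.z) == 0:
            raise ValueError("refusing to write an empty profile")
        data = {"z_angstrom": profile.z}
        for name, arr in profile.mass_densities.items():
            data[f"mass_{name}"] = arr
        for name, arr in profile.charge_densities.items():
            data[f"charge_{name}"] = arr
        df = pd.DataFrame(data)
        for col in df.columns:
            bad = np.flatnonzero(~np.isfinite(df[col].to_numpy()))
            if len(bad):
                raise ValueError(
                    f"profile column {col!r} has non-finite value at index {bad[0]}"
                )
        meta = {
            "format": "lamella density profiles",
            "centering": profile.centering,
            "units": "mass:kg_m3 charge:e_A3",
        }
        if profile.area_per_lipid is not None:
            meta["area_per_lipid_A2"] = repr(profile.area_per_lipid)
        if profile.temperature is not None:
            meta["temperature_K"] = repr(profile.temperature)
    else:
        raise TypeError(f"unsupported profile type {type(profile)!r}")
    _write_tsv(df, path, meta)


def read_nsld_profile(path) -> NSLDProfile:
    df, meta = _read_tsv(path)
    if "z_angstrom" not in df.columns or "rho_rel" not in df.columns:
        raise TableFormatError(f"{path} is not an NSLD profile table")
    signs = None
    if "signs" in meta:
        signs = np.array([int(s) for s in meta["signs"].split(",")])
    return NSLDProfile(
        z=df["z_angstrom"].to_numpy(),
        rho=df["rho_rel"].to_numpy(),
        d=float(meta["d_angstrom"]),
        n_orders_used=int(meta.get("n_orders_used", 0)),
        signs_used=signs,
    )


def read_density_profiles(path) -> DensityProfileSet:
    df, meta = _read_tsv(path)
    if "z_angstrom" not in df.columns:
        raise TableFormatError(f"{path} is not a density profile table")
    mass = {}
    charge = {}
    for col in df.columns:
        if col.startswith("mass_"):
            mass[col[5:]] = df[col].to_numpy()
        elif col.startswith("charge_"):
            charge[col[7:]] = df[col].to_numpy()
    apl = meta.get("area_per_lipid_A2")
    temp = meta.get("temperature_K")
    return DensityProfileSet(
        z=df["z_angstrom"].to_numpy(),
        mass_densities=mass,
        charge_densities=charge,
        centering=meta.get("centering", "bilayer"),
        area_per_lipid=float(apl) if apl is not None else None,
        temperature=float(temp) if temp is not None else None,
    )


def write_pressure_table(points, path, metadata=None) -> None:
    df = pd.DataFrame(
        [
            dict(pi_pa=p.pi, d_w_angstrom=p.d_w, d_w_err=p.d_w_err, phase_label=p.phase_label)
            for p in points
        ],
        columns=["pi_pa", "d_w_angstrom", "d_w_err", "phase_label"],
    )
    meta = {"format": "lamella pressure-distance table"}
    meta.update(metadata or {})
    _write_tsv(df, path, meta)


def read_pressure_table(path):
    from .datamodel import PressurePoint

    df, _ = _read_tsv(path)
    needed = {"pi_pa", "d_w_angstrom"}
    if not needed.issubset(df.columns):
        raise TableFormatError(f"{path} is not a pressure-distance table")
    return [
        PressurePoint(
            pi=float(r.pi_pa),
            d_w=float(r.d_w_angstrom),
            d_w_err=float(getattr(r, "d_w_err", 0.0) or 0.0),
            phase_label=str(getattr(r, "phase_label", "unassigned")),
        )
        for r in df.itertuples()
    ]


def write_sheet_maps(maps, path, metadata=None) -> None:
    """Bragg-sheet maps in long TSV format (sheet, q_z_offset, q_par, intensity)."""
    rows = []
    for m in maps:
        for i, dz in enumerate(m.q_z_offsets):
            for j, q in enumerate(m.q_par):
                rows.append(
                    dict(
                        sheet=m.sheet,
                        q_z_offset_invA=dz,
                        q_par_invA=q,
                        intensity=m.intensity[i, j],
                    )
                )
    df = pd.DataFrame(
        rows, columns=["sheet", "q_z_offset_invA", "q_par_invA", "intensity"]
    )
    meta = {"format": "lamella bragg-sheet map"}
    if maps:
        meta["d_angstrom"] = repr(maps[0].d)
        meta["temperature_K"] = repr(maps[0].temperature)
    meta.update(metadata or {})
    _write_tsv(df, path, meta)


def read_sheet_maps(path):
    from .datamodel import BraggSheetMap

    df, meta = _read_tsv(path)
    if "sheet" not in df.columns:
        raise TableFormatError(f"{path} is not a Bragg-sheet map table")
    out = []
    for sheet, group in df.groupby("sheet", sort=True):
        offsets = np.unique(group["q_z_offset_invA"].to_numpy())
        q_par = np.unique(group["q_par_invA"].to_numpy())
        pivot = group.pivot_table(
            index="q_z_offset_invA", columns="q_par_invA", values="intensity"
        )
        out.append(
            BraggSheetMap(
                sheet=int(sheet),
                q_z_offsets=offsets,
                q_par=q_par,
                intensity=pivot.to_numpy(),
                d=float(meta["d_angstrom"]),
                temperature=float(meta["temperature_K"]),
            )
        )
    return out


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys warn, missing keys default."""
    path = Path(path)
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ValueError(f"malformed config {path}{line}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a key-value mapping")
    known = RunConfig.field_names()
    unknown = sorted(set(raw) - set(known))
    if unknown:
        log.warning("ignoring unknown config key(s): %s", unknown)
    kwargs = {k: v for k, v in raw.items() if k in known}
    cfg = RunConfig(**kwargs)
    log.info("effective config: %s", dataclasses.asdict(cfg))
    return cfg
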