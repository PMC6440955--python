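"""Readers and writers for the package's public file formats.

Trajectories travel as PDB topology + DCD/XTC coordinates (mdtraj).
Tabular data travel as CSV with an explicit unit header line
(``# units: column=unit,...``) above the column row; readers reject
files without it, warn about unknown extra columns, and preserve them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import mdtraj as md

from .exchange_kinetics import FragmentIonSeries, OverallExchangeCurve
from .trajectory import BACKBONE_NAMES, HelixTrajectory

__all__ = [
    "read_trajectory",
    "write_csv",
    "read_csv",
    "write_overall_curve",
    "read_overall_curve",
    "write_fragments",
    "read_fragments",
    "write_profile",
]


def read_trajectory(
    topology_path, coordinates_path=None, frame_interval_ps: float = 10.0
) -> HelixTrajectory:
    """Load a helix trajectory from PDB topology (+ DCD/XTC coordinates).

    Validates that every peptide residue provides the backbone atoms the
    analyses need (N, CA, C; H and O may be absent at caps only).
    """
    topology_path = str(topology_path)
    if coordinates_path is None:
        traj = md.load(topology_path)
    else:
        coordinates_path = str(coordinates_path)
        try:
            traj = md.load(coordinates_path, top=topology_path)
        except Exception as err:  # mdtraj raises format-specific errors
            raise ValueError(
                f"failed to read {coordinates_path!r} against "
                f"{topology_path!r}: {err}"
            ) from None
    htraj = HelixTrajectory(traj=traj, frame_interval_ps=frame_interval_ps)
    missing = []
    for res in htraj.residue_numbers:
        for name in ("N", "CA", "C"):
            if not htraj.has_atom(res, name):
                missing.append((res, name))
    if missing:
        raise ValueError(f"missing backbone atoms: {missing[:5]}")
    return htraj


# -------------------------------------------------------------- CSV core


def write_csv(path, frame: pd.DataFrame, units: dict):
    """CSV with a leading unit header line; column order is preserved
    and rows are written exactly as ordered (bit-stable output)."""
    unknown = set(frame.columns) - set(units)
    if unknown:
        raise ValueError(f"no units declared for columns: {sorted(unknown)}")
    header = "# units: " + ",".join(f"{c}={units[c]}" for c in frame.columns)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def read_csv(path, required: tuple = ()) -> tuple[pd.DataFrame, dict]:
    """Read a unit-headed CSV; returns (frame, units)."""
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# units:"):
            raise ValueError(f"{path}: missing '# units:' header line")
        units = dict(
            item.split("=", 1) for item in first[len("# units:"):].split(",")
            if item.strip()
        )
        units = {k.strip(): v.strip() for k, v in units.items()}
        frame = pd.read_csv(fh)
    missing = set(required) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    extra = set(frame.columns) - set(units)
    if extra:
        warnings.warn(
            f"{path}: columns without declared units preserved: {sorted(extra)}",
            stacklevel=2,
        )
    return frame, units


# --------------------------------------------------------- typed tables


def write_overall_curve(path, curve: OverallExchangeCurve):
    frame = pd.DataFrame(
        {
            "time_min": curve.times,
            "mean_D": curve.remaining_deuterons,
            "sem": curve.sem if curve.sem is not None else np.nan,
            "n": curve.n_replicates,
        }
    )
    write_csv(path, frame, {"time_min": "min", "mean_D": "D", "sem": "D",
                            "n": "count"})


def read_overall_curve(path) -> OverallExchangeCurve:
    frame, _ = read_csv(path, required=("time_min", "mean_D"))
    sem = frame["sem"].to_numpy() if "sem" in frame else None
    n = int(frame["n"].iloc[0]) if "n" in frame else 1
    return OverallExchangeCurve(
        times=frame["time_min"].to_numpy(),
        remaining_deuterons=frame["mean_D"].to_numpy(),
        sem=sem,
        n_replicates=n,
    )


def write_fragments(path, fragments):
    rows = []
    for f in fragments:
        for t, d in zip(f.times, f.deuterons):
            rows.append((f.ion_type, f.fragment_length, f.replicate_id, t, d))
    frame = pd.DataFrame(
        rows, columns=["ion_type", "length", "replicate", "time_min",
                       "deuterons"]
    )
    write_csv(
        path, frame,
        {"ion_type": "c|z", "length": "residues", "replicate": "id",
         "time_min": "min", "deuterons": "D"},
    )


def read_fragments(path) -> list[FragmentIonSeries]:
    frame, _ = read_csv(
        path, required=("ion_type", "length", "replicate", "time_min",
                        "deuterons")
    )
    out = []
    for (ion, length, rep), grp in frame.groupby(
        ["ion_type", "length", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_min")
        out.append(
            FragmentIonSeries(
                ion_type=str(ion),
                fragment_length=int(length),
                times=grp["time_min"].to_numpy(),
                deuterons=grp["deuterons"].to_numpy(),
                replicate_id=int(rep),
            )
        )
    return out


def write_profile(path, residue_numbers, values, units: str,
                  ci_lower=None, ci_upper=None, flags: dict | None = None,
                  value_name: str = "value"):
    """Generic per-residue profile table (rates, dG, occupancies...)."""
    n = len(residue_numbers)
    frame = pd.DataFrame(
        {
            "residue_number": residue_numbers,
            value_name: values,
            "ci_lo": ci_lower if ci_lower is not None else np.full(n, np.nan),
            "ci_hi": ci_upper if ci_upper is not None else np.full(n, np.nan),
            "flag": [
                (flags or {}).get(int(r), "") for r in residue_numbers
            ],
        }
    )
    write_csv(
        path, frame,
        {"residue_number": "C99", value_name: units, "ci_lo": units,
         "ci_hi": units, "flag": "text"},
    )
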