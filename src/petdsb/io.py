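"""File formats of the pipeline.

All tabular artifacts are UTF-8 CSV with a header row, comma separators
and '.' decimals, at full double precision; nested reports are JSON.  A
dataset directory holds volunteers.csv, tac.csv, doses.json, foci.csv,
saf_table.csv and manifest.json; an analysis directory holds rates.csv,
excess.csv, tests.csv and summary.json.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .blood import TimeActivityCurve, Volunteer
from .cohort import StudyData
from .dosimetry import DoseReport, TubeSAFTable

__all__ = [
    "write_study",
    "read_study",
    "write_tac_csv",
    "read_tac_csv",
    "write_saf_table",
    "read_saf_table",
    "write_analysis",
]

TAC_COLUMNS = ["volunteer_id", "frame_start_s", "frame_end_s", "conc_kBq_per_ml"]
VOLUNTEER_COLUMNS = ["id", "arm", "sex", "age", "height_m", "weight_kg", "administered_activity_MBq"]


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required file missing: {path}")
    return path


# --- volunteers -------------------------------------------------------------


def write_volunteers_csv(volunteers: list[Volunteer], path: Path) -> None:
    rows = [
        {
            "id": v.id,
            "arm": v.arm,
            "sex": v.sex,
            "age": v.age,
            "height_m": v.height_m,
            "weight_kg": v.weight_kg,
            "administered_activity_MBq": v.administered_activity_MBq,
        }
        for v in volunteers
    ]
    pd.DataFrame(rows, columns=VOLUNTEER_COLUMNS).to_csv(path, index=False)


def read_volunteers_csv(path: Path) -> list[Volunteer]:
    df = pd.read_csv(_require(path), float_precision="round_trip")
    out = []
    for row in df.itertuples():
        act = None if pd.isna(row.administered_activity_MBq) else float(row.administered_activity_MBq)
        out.append(
            Volunteer(
                id=str(row.id),
                arm=str(row.arm),
                sex=str(row.sex),
                age=float(row.age),
                height_m=float(row.height_m),
                weight_kg=float(row.weight_kg),
                administered_activity_MBq=act,
            )
        )
    return out


# --- TACs -------------------------------------------------------------------


def write_tac_csv(tacs: dict[str, TimeActivityCurve], path: Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "volunteer_id": tac.volunteer_id,
                "frame_start_s": tac.frame_start_s,
                "frame_end_s": tac.frame_end_s,
                "conc_kBq_per_ml": tac.conc_kBq_per_ml,
            }
        )
        for tac in tacs.values()
    ]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TAC_COLUMNS)
    df.to_csv(path, index=False)


def read_tac_csv(path: Path) -> dict[str, TimeActivityCurve]:
    df = pd.read_csv(_require(path), float_precision="round_trip")
    missing = set(TAC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"TAC CSV lacks columns: {sorted(missing)}")
    out: dict[str, TimeActivityCurve] = {}
    for vid, grp in df.groupby("volunteer_id", sort=False):
        grp = grp.sort_values("frame_start_s")
        out[str(vid)] = TimeActivityCurve(
            volunteer_id=str(vid),
            frame_start_s=grp["frame_start_s"].to_numpy(float),
            frame_end_s=grp["frame_end_s"].to_numpy(float),
            conc_kBq_per_ml=grp["conc_kBq_per_ml"].to_numpy(float),
        )
    return out


# --- SAF table --------------------------------------------------------------


def write_saf_table(table: TubeSAFTable, path: Path) -> None:
    n = len(table.volumes_ml)
    se_b = table.se_beta or (np.nan,) * n
    se_p = table.se_photon or (np.nan,) * n
    pd.DataFrame(
        {
            "volume_ml": table.volumes_ml,
            "phi_beta": table.phi_beta,
            "phi_photon": table.phi_photon,
            "se_beta": se_b,
            "se_photon": se_p,
        }
    ).to_csv(path, index=False)


def read_saf_table(path: Path) -> TubeSAFTable:
    df = pd.read_csv(_require(path), float_precision="round_trip")
    return TubeSAFTable(
        volumes_ml=tuple(df["volume_ml"]),
        phi_beta=tuple(df["phi_beta"]),
        phi_photon=tuple(df["phi_photon"]),
        se_beta=tuple(df["se_beta"]),
        se_photon=tuple(df["se_photon"]),
    )


# --- dataset directory ------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_study(study: StudyData, outdir: str | Path, config_dict: dict | None = None) -> Path:
    """Write a full dataset directory, including a manifest with the seed,
    package version and per-file checksums."""
    from . import __version__

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_volunteers_csv(study.volunteers, out / "volunteers.csv")
    write_tac_csv(study.tacs, out / "tac.csv")
    with open(out / "doses.json", "w", encoding="utf-8") as fh:
        json.dump({vid: rep.to_dict() for vid, rep in study.dose_reports.items()}, fh, indent=1)
    study.foci.to_csv(out / "foci.csv", index=False)
    write_saf_table(study.saf_table, out / "saf_table.csv")
    files = ["volunteers.csv", "tac.csv", "doses.json", "foci.csv", "saf_table.csv"]
    manifest = {
        "seed": study.seed,
        "version": __version__,
        "config": config_dict,
        "checksums": {f: _sha256(out / f) for f in files},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def read_study(indir: str | Path) -> StudyData:
    """Read a dataset directory back into memory; every missing file is
    reported by name."""
    d = Path(indir)
    volunteers = read_volunteers_csv(d / "volunteers.csv")
    tacs = read_tac_csv(d / "tac.csv")
    with open(_require(d / "doses.json"), encoding="utf-8") as fh:
        doses = {vid: DoseReport.from_dict(rep) for vid, rep in json.load(fh).items()}
    foci = pd.read_csv(_require(d / "foci.csv"))
    saf = read_saf_table(d / "saf_table.csv")
    seed = None
    manifest = d / "manifest.json"
    if manifest.exists():
        with open(manifest, encoding="utf-8") as fh:
            seed = json.load(fh).get("seed")
    return StudyData(volunteers=volunteers, tacs=tacs, dose_reports=doses, foci=foci, saf_table=saf, seed=seed)


# --- analysis directory -----------------------------------------------------


def write_analysis(results: dict, outdir: str | Path) -> Path:
    """Write rates.csv, excess.csv, tests.csv and summary.json from the
    output of :func:`petdsb.stats.summarize_study`."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results["rates"].to_csv(out / "rates.csv", index=False)
    results["excess"].to_csv(out / "excess.csv", index=False)
    results["tests"].to_csv(out / "tests.csv", index=False)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(results["summary"], fh, indent=1, sort_keys=True, allow_nan=True)
    return out
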