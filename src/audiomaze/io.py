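"""Reading and writing the pipeline's on-disk formats.

All tabular outputs are plain text with headers: trial samples as CSV,
cohort manifests and fits as TSV, comparison reports as TSV plus JSON.
A run's effective configuration is echoed into its output directory as
``config.echo.json`` together with SHA-256 checksums of every file written,
so a run can be reproduced and verified bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .comparison import comparison_records
from .simulate import TrialRecord


def write_cohort(
    records: list[TrialRecord],
    manifest: pd.DataFrame,
    out_dir: str | Path,
) -> Path:
    """Write trial CSVs plus the cohort manifest TSV; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials_dir = out / "trials"
    trials_dir.mkdir(exist_ok=True)
    paths = []
    for rec in records:
        name = f"{rec.participant_id}_{rec.maze_id}_t{rec.trial_index}.csv"
        rec.to_csv(trials_dir / name)
        paths.append(str(Path("trials") / name))
    manifest = manifest.copy()
    manifest["trial_csv_path"] = paths
    manifest_path = out / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def read_cohort(manifest_path: str | Path) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Load a cohort back from its manifest; corrupt trials are skipped."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    base = manifest_path.parent
    records = []
    kept = []
    for i, row in manifest.iterrows():
        path = base / row["trial_csv_path"]
        try:
            rec = TrialRecord.from_csv(
                path,
                participant_id=row["participant_id"],
                navigator_style=row["navigator_style"],
                maze_id=row["maze_id"],
                trial_index=int(row["trial_index"]),
            )
        except (OSError, ValueError, KeyError) as err:
            import warnings

            warnings.warn(f"skipping trial {path}: {err}")
            continue
        records.append(rec)
        kept.append(i)
    return records, manifest.loc[kept].reset_index(drop=True)


def write_motion_series(series, path: str | Path) -> Path:
    """Write a 2 Hz motion series with per-step kinematics as CSV.

    Columns: time_s, com_x, com_y, hand_x, hand_y, head_x, head_y,
    hand_beep, head_beep, d, theta.  The first sample has no step, so its
    d and theta are empty.
    """
    import numpy as np

    from .preprocess import motion_vectors

    mv = motion_vectors(series)
    d = np.concatenate([[np.nan], mv.d])
    theta = np.concatenate([[np.nan], mv.theta])
    frame = pd.DataFrame(
        {
            "time_s": series.times,
            "com_x": series.torso_com[:, 0],
            "com_y": series.torso_com[:, 1],
            "hand_x": series.hand[:, 0],
            "hand_y": series.hand[:, 1],
            "head_x": series.head[:, 0],
            "head_y": series.head[:, 1],
            "hand_beep": series.hand_beep.astype(int),
            "head_beep": series.head_beep.astype(int),
            "d": d,
            "theta": theta,
        }
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def write_fits(fits: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fits.to_csv(path, sep="\t", index=False)
    return path


def read_fits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_report(results, out_dir: str | Path, name: str = "comparison") -> Path:
    """Write a comparison report as both tidy TSV and JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = comparison_records(results)
    table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    (out / f"{name}.json").write_text(
        json.dumps(table.to_dict(orient="records"), indent=2, default=str)
    )
    return out / f"{name}.tsv"


def echo_config(config: dict, out_dir: str | Path) -> Path:
    """Serialize the effective run configuration into the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "config.echo.json"
    path.write_text(json.dumps(config, indent=2, sort_keys=True, default=str))
    return path


def write_checksums(out_dir: str | Path) -> Path:
    """SHA-256 checksums of every file under ``out_dir`` (reproducibility aid)."""
    out = Path(out_dir)
    lines = []
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "checksums.txt":
            digest = hashlib.sha256(p.read_bytes()).hexdigest()
            lines.append(f"{digest}  {p.relative_to(out)}")
    path = out / "checksums.txt"
    path.write_text("\n".join(lines) + "\n")
    return path
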