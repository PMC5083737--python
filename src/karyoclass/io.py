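"""Feature-table readers/writers and run provenance.

CSV dialect: comma-separated, UTF-8, '.' decimal, mandatory header, floats
at 9 significant digits.  Tissue-level tables carry ``tissue_id``, an
optional ``class`` column restricted to {CP, IPMN, PC}, and numeric feature
columns; nucleus-level tables add ``nucleus_id``.
"""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .multinomial import CLASS_ORDER
from .synthetic import TissueSample

VALID_CLASSES = set(CLASS_ORDER)


def read_feature_table(path: str | Path, require_class: bool = False) -> pd.DataFrame:
    """Read and validate a tissue- or nucleus-level feature CSV.

    Raises ValueError naming the offending column/row/value on missing
    columns, non-numeric features, or unknown class labels.
    """
    path = Path(path)
    table = pd.read_csv(path)
    if "tissue_id" not in table.columns:
        raise ValueError(f"{path}: missing required column 'tissue_id'")
    if require_class and "class" not in table.columns:
        raise ValueError(f"{path}: missing required column 'class'")
    if "class" in table.columns:
        bad = table.loc[~table["class"].isin(VALID_CLASSES), "class"]
        if len(bad):
            row = int(bad.index[0])
            raise ValueError(
                f"{path}: unknown class label {bad.iloc[0]!r} at row {row} "
                f"(expected one of {sorted(VALID_CLASSES)})"
            )
    id_cols = {"tissue_id", "nucleus_id", "class"}
    feature_cols = [c for c in table.columns if c not in id_cols]
    if not feature_cols:
        raise ValueError(f"{path}: no feature columns found")
    for col in feature_cols:
        numeric = pd.to_numeric(table[col], errors="coerce")
        if numeric.isna().any() and not table[col].isna().any():
            row = int(numeric.index[numeric.isna()][0])
            raise ValueError(
                f"{path}: non-numeric value {table[col][row]!r} in column "
                f"{col!r} at row {row}"
            )
        if numeric.isna().any():
            row = int(numeric.index[numeric.isna()][0])
            raise ValueError(f"{path}: missing value in column {col!r} at row {row}")
        table[col] = numeric
    return table


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.9g")


def to_tissue_samples(table: pd.DataFrame) -> list[TissueSample]:
    """Group a nucleus-level table into per-tissue samples."""
    if "nucleus_id" not in table.columns:
        raise ValueError("nucleus-level table requires a 'nucleus_id' column")
    samples = []
    for tid, group in table.groupby("tissue_id", sort=False):
        truth = group["class"].iloc[0] if "class" in group.columns else None
        features = group.drop(columns=[c for c in ("tissue_id", "class") if c in group])
        samples.append(
            TissueSample(tissue_id=str(tid), true_class=truth, features=features.reset_index(drop=True))
        )
    return samples


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    subcommand: str,
    params: dict,
    inputs: list[str | Path] = (),
    outputs: list[str | Path] = (),
) -> Path:
    """Write the provenance manifest for one CLI run (one per output dir)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "karyoclass",
        "version": __version__,
        "subcommand": subcommand,
        "parameters": params,
        "inputs": {str(p): _digest(Path(p)) for p in inputs if Path(p).exists()},
        "outputs": {str(p): _digest(Path(p)) for p in outputs if Path(p).exists()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def save_json(obj: dict, path: str | Path) -> None:
    def _default(x):
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, np.ndarray):
            return x.tolist()
        raise TypeError(f"not JSON-serializable: {type(x)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
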