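"""Plain-text readers/writers, study configuration, and report formats.

Conventions: region indices and frames are 0-based; matrices are TSV with a
header row of column ids and an index column of region ids; manifests are
CSV with columns subject_id, group, age, path (path relative to the
manifest's directory).  Every report carries the config hash and seed; no
wall-clock timestamps enter persisted outputs, so identical config + seed
reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._core import (
    DimensionError,
    Parcellation,
    StructuralConnectome,
    ValidationError,
)


def write_matrix_tsv(path: str | Path, matrix: np.ndarray, fmt: str = "%.6f") -> None:
    m = np.asarray(matrix)
    df = pd.DataFrame(m)
    df.index.name = "region_id"
    float_format = fmt if "%" in fmt else None
    df.to_csv(path, sep="\t", float_format=float_format)


def read_matrix_tsv(
    path: str | Path, expect_square: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Read a numeric TSV matrix; returns (matrix, row ids).

    Raises on ragged rows, non-numeric cells, and (when ``expect_square``)
    non-square or asymmetric bodies.  Files without a header/index column
    are accepted when fully numeric.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = path.read_text().splitlines()
    rows = [ln.split("\t") for ln in lines if ln.strip() != ""]
    if not rows:
        raise ValidationError(f"{path}: empty matrix file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        bad = next(k for k, r in enumerate(rows) if len(r) != len(rows[0]))
        raise ValidationError(f"{path}: ragged row at line {bad + 1}")

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_is_number(tok) for tok in rows[0])
    body = rows[1:] if has_header else rows
    has_index = has_header and rows[0][0] in ("", "region_id")
    ids = []
    values = []
    for k, r in enumerate(body):
        cells = r[1:] if has_index else r
        ids.append(r[0] if has_index else str(k))
        for tok in cells:
            if not _is_number(tok):
                raise ValidationError(
                    f"{path}: non-numeric cell {tok!r} at line {k + (2 if has_header else 1)}"
                )
        values.append([float(tok) for tok in cells])
    matrix = np.asarray(values, dtype=float)
    if expect_square:
        if matrix.shape[0] != matrix.shape[1]:
            raise DimensionError(f"{path}: expected square matrix, got {matrix.shape}")
        if not np.allclose(matrix, matrix.T):
            raise ValidationError(f"{path}: matrix is not symmetric")
    return matrix, np.asarray(ids, dtype=object)


def write_labels(path: str | Path, parc: Parcellation) -> None:
    parc.to_frame().to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path, n_regions: int | None = None) -> Parcellation:
    """Read a region label TSV and validate the 8-system vocabulary."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    parc = Parcellation.from_frame(df)
    if n_regions is not None and parc.n_regions != n_regions:
        raise DimensionError(
            f"{path}: {parc.n_regions} labels but matrices have {n_regions} regions"
        )
    return parc


def read_structural(path: str | Path, n_regions: int | None = None) -> StructuralConnectome:
    matrix, _ = read_matrix_tsv(path, expect_square=True)
    sc = StructuralConnectome(weights=matrix)
    if n_regions is not None and sc.n_regions != n_regions:
        raise DimensionError(f"{path}: structural matrix size {sc.n_regions} != {n_regions}")
    return sc


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = {"subject_id", "group", "age", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: manifest missing columns {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate subject ids")
    return df


def write_raster_tsv(path: str | Path, active: np.ndarray) -> None:
    write_matrix_tsv(path, active.astype(int), fmt="%d")


@dataclass
class StudyConfig:
    """Single source of all stage parameters for one study run.

    Path fields are resolved relative to the config file's directory when
    loaded with :func:`load_config`.
    """

    manifest: str = "manifest.csv"
    labels: str = "labels.tsv"
    structural: str = "sc.tsv"
    output_dir: str = "results"
    input_kind: str = "series"  # "series" (z-score + threshold) or "raster"
    threshold: float = 2.0
    min_cc_size: int = 2
    sc_threshold: float = 0.0
    attribution_frac: float = 0.20
    sd_variant: str = "mean_cc"
    std_variant: str = "region_pairs"
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_kind not in ("series", "raster"):
            raise ValidationError("input_kind must be 'series' or 'raster'")
        if not 0 < self.attribution_frac <= 1:
            raise ValidationError("attribution_frac must lie in (0, 1]")
        if self.n_perm <= 0 or self.min_cc_size < 1:
            raise ValidationError("n_perm and min_cc_size must be positive")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")


def config_hash(config: StudyConfig) -> str:
    blob = yaml.safe_dump(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> StudyConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    known = set(StudyConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = StudyConfig(**raw)
    base = path.parent
    for key in ("manifest", "labels", "structural", "output_dir"):
        setattr(cfg, key, str((base / getattr(cfg, key)).resolve()))
    return cfg


def save_config(path: str | Path, config: StudyConfig) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))
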