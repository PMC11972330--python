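"""TSV readers/writers, run configuration and the run manifest.

All files are plain tab-separated UTF-8 with '.' decimals. Numeric output
uses repr-round-trippable formatting so a write/read cycle is lossless.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import DesignError, ParseError
from .metrics import METRIC_NAMES, MetricParams
from .normalize import ProfileSet

__all__ = [
    "RunConfig",
    "read_counts",
    "read_expression",
    "read_lengths",
    "read_sample_sheet",
    "write_matrix",
    "write_lengths",
    "write_sample_sheet",
    "write_truth",
    "write_profiles",
    "write_distance_table",
    "write_screen_table",
    "write_manifest",
]


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (YAML/JSON-serializable)."""

    variance_threshold: float = 0.1
    alpha: float = 0.01
    metrics: tuple[str, ...] = METRIC_NAMES
    aggregation: str = "mean"
    conditions: tuple[str, str] = ("WT", "KO")
    metric_params: MetricParams = field(default_factory=MetricParams)
    expression_input: bool = False  # input matrix already log2(tpm+1)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metrics"] = list(self.metrics)
        d["conditions"] = list(self.conditions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "metric_params" in d and isinstance(d["metric_params"], dict):
            d["metric_params"] = MetricParams(**d["metric_params"])
        if "metrics" in d:
            d["metrics"] = tuple(d["metrics"])
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        return cls(**d)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------
def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"input file not found: {path}")
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse TSV ({exc})") from exc


def _check_unique(index: pd.Index, what: str, path) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        # +2: 1-based and header line
        line = int(np.flatnonzero(index == dup)[-1]) + 2
        raise ParseError(f"{path}: duplicate {what} {dup!r} (line {line})")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample raw count matrix (first column gene_id)."""
    df = _read_tsv(path, index_col=0)
    df.index.name = "gene_id"
    _check_unique(df.index, "gene_id", path)
    _check_unique(pd.Index(df.columns), "sample_id", path)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ParseError(f"{path}: non-numeric entries in count matrix")
    bad = np.argwhere(~(np.isfinite(values) & (values >= 0)))
    if bad.size:
        r, c = bad[0]
        raise ParseError(
            f"{path}: invalid count at line {r + 2}, column {df.columns[c]!r} "
            f"(gene {df.index[r]!r}): {values[r, c]!r}"
        )
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample expression matrix (log2(tpm+1) scale)."""
    df = _read_tsv(path, index_col=0)
    df.index.name = "gene_id"
    _check_unique(df.index, "gene_id", path)
    _check_unique(pd.Index(df.columns), "sample_id", path)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or not np.all(np.isfinite(values)):
        raise ParseError(f"{path}: expression matrix must be finite numeric")
    return df


def read_lengths(path: str | Path) -> pd.Series:
    """Read a gene-length table (gene_id, length_bp)."""
    df = _read_tsv(path)
    if "gene_id" not in df.columns or "length_bp" not in df.columns:
        raise ParseError(f"{path}: expected columns gene_id, length_bp; got {list(df.columns)}")
    df = df.set_index("gene_id")
    _check_unique(df.index, "gene_id", path)
    s = df["length_bp"]
    bad = ~(pd.to_numeric(s, errors="coerce") > 0)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise ParseError(f"{path}: non-positive gene length at line {line}")
    return s.astype(float)


def read_sample_sheet(
    path: str | Path, conditions: tuple[str, str] = ("WT", "KO")
) -> pd.DataFrame:
    """Read and validate the sample sheet (sample_id, condition, timepoint, replicate)."""
    df = _read_tsv(path)
    expected = {"sample_id", "condition", "timepoint", "replicate"}
    if not expected.issubset(df.columns):
        raise ParseError(
            f"{path}: expected columns {sorted(expected)}; got {list(df.columns)}"
        )
    _check_unique(pd.Index(df["sample_id"]), "sample_id", path)
    bad = ~df["condition"].isin(conditions)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise ParseError(
            f"{path}: condition outside {list(conditions)} at line {line}: "
            f"{df['condition'].iloc[np.flatnonzero(bad)[0]]!r}"
        )
    df["timepoint"] = pd.to_numeric(df["timepoint"], errors="raise")
    tp_sets = {c: set(df.loc[df["condition"] == c, "timepoint"]) for c in conditions}
    if tp_sets[conditions[0]] != tp_sets[conditions[1]]:
        only = sorted(tp_sets[conditions[0]].symmetric_difference(tp_sets[conditions[1]]))
        raise DesignError(f"{path}: timepoints present in one condition only: {only}")
    return df


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------
_FLOAT_FMT = "%.17g"


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format=_FLOAT_FMT)


def write_lengths(lengths: pd.Series, path: str | Path) -> None:
    lengths.rename("length_bp").to_csv(path, sep="\t", index_label="gene_id")


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_profiles(profiles: ProfileSet, path: str | Path) -> None:
    """Intermediate profiles TSV: raw and scaled series per gene x condition."""
    t = profiles.time_vector
    rows = []
    for i, gid in enumerate(profiles.gene_ids):
        for cond, arr in (("WT", profiles.wt), ("KO", profiles.ko)):
            row = {"gene_id": gid, "condition": cond}
            for j, tp in enumerate(t):
                row[f"t{j + 1}"] = arr[i, j]
            row["variance14"] = profiles.variance14[i]
            row["scaled"] = profiles.scaled
            if profiles.e_min is not None:
                row["e_min"] = profiles.e_min[i]
                row["e_max"] = profiles.e_max[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_distance_table(
    distances: pd.DataFrame,
    path: str | Path,
    params: MetricParams,
    time_vector: np.ndarray,
) -> None:
    """Distance table TSV with a '# key=value' metadata header block."""
    p = params.resolve(len(time_vector))
    meta = {
        "time_vector": ",".join(f"{v:g}" for v in time_vector),
        "acf_max_lag": p.acf_max_lag,
        "fourier_n_coef": p.fourier_n_coef,
        "cdm_alphabet_size": p.cdm_alphabet_size,
        "cdm_compressor": p.cdm_compressor,
        "cdm_compressor_impl": (
            f"lzma raw lzma2 preset9 (liblzma, python {platform.python_version()})"
            if p.cdm_compressor == "lzma"
            else "zlib level 9"
        ),
        "cid_epsilon": p.cid_epsilon,
        "per_n_freq": p.per_n_freq,
        "frechet_embedding": p.frechet_embedding,
    }
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        distances.to_csv(fh, sep="\t", index_label="gene_id", float_format=_FLOAT_FMT)


def write_screen_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id", float_format=_FLOAT_FMT)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: dict,
    inputs: dict[str, str | Path],
    outputs: dict[str, str | Path],
    funnel: dict[str, int] | None = None,
) -> None:
    """Machine-readable run manifest: config echo, versions, input checksums."""
    from . import __version__

    manifest = {
        "tool": "tempodiff",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": config,
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in inputs.items()},
        "outputs": {k: str(v) for k, v in outputs.items()},
        "funnel": funnel or {},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
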