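"""Readers, writers and the run manifest.

Delimited text (CSV/TSV) is read with rows as samples: an optional header
row and an optional leading non-numeric ID column are detected.
Matrix-Market files follow the single-cell convention (features x
samples) and are transposed on load so samples are rows everywhere;
optional ``features``/``barcodes`` sidecar files provide names.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix == ".tsv":
        return "tsv"
    return "csv"


def _read_delimited(path: Path, sep: str):
    try:
        raw = pd.read_csv(path, sep=sep, header=None, dtype=str,
                          skip_blank_lines=True)
    except Exception as exc:
        raise DataError(f"{path}: cannot parse: {exc}") from exc
    if raw.isna().any().any():
        bad = int(np.where(raw.isna().any(axis=1))[0][0])
        raise DataError(f"{path}: ragged or missing cells near line {bad + 1}")

    def numeric(frame):
        return frame.apply(pd.to_numeric, errors="coerce")

    body = raw
    header = None
    first_row = numeric(raw.iloc[[0]])
    if first_row.isna().any().any():  # non-numeric first row = header
        header = raw.iloc[0].tolist()
        body = raw.iloc[1:].reset_index(drop=True)
    ids = None
    first_col = pd.to_numeric(body.iloc[:, 0], errors="coerce")
    if first_col.isna().any():  # non-numeric first column = sample IDs
        ids = body.iloc[:, 0].tolist()
        body = body.iloc[:, 1:]
        if header is not None:
            header = header[1:]
    X = numeric(body)
    if X.isna().any().any():
        r, c = map(int, np.argwhere(X.isna().to_numpy())[0])
        raise DataError(
            f"{path}: non-numeric cell at data row {r + 1}, column {c + 1}"
        )
    if ids is None:
        ids = [str(i + 1) for i in range(len(X))]
    return X.to_numpy(dtype=float), ids, header


def _read_mtx(path: Path):
    from scipy.io import mmread

    try:
        M = mmread(str(path))
    except Exception as exc:
        raise DataError(f"{path}: invalid Matrix-Market file: {exc}") from exc
    M = np.asarray(M.todense()) if hasattr(M, "todense") else np.asarray(M)
    n_feat, n_samp = M.shape
    ids = None
    for name in ("barcodes.tsv", "barcodes.txt"):
        side = path.parent / name
        if side.exists():
            ids = [ln.split("\t")[0] for ln in
                   side.read_text().strip().splitlines()]
            if len(ids) != n_samp:
                raise DataError(
                    f"{side}: has {len(ids)} barcodes but the matrix has "
                    f"{n_samp} sample columns"
                )
            break
    for name in ("features.tsv", "genes.tsv"):
        side = path.parent / name
        if side.exists():
            feats = side.read_text().strip().splitlines()
            if len(feats) != n_feat:
                raise DataError(
                    f"{side}: has {len(feats)} features but the matrix has "
                    f"{n_feat} feature rows"
                )
            break
    if ids is None:
        ids = [str(i + 1) for i in range(n_samp)]
    return M.T.astype(float), ids  # samples become rows


def read_matrix(path, fmt: str | None = None, orientation: str = "auto"):
    """Load a feature matrix; returns ``(X, sample_ids)`` with samples as rows.

    ``orientation`` applies to delimited files: ``samples-rows`` (default
    reading) or ``samples-columns`` (transpose after load). Matrix-Market
    input is always features x samples and is transposed.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"{path}: no such file")
    fmt = _detect_format(path, fmt)
    if fmt == "mtx":
        return _read_mtx(path)
    X, ids, _ = _read_delimited(path, "\t" if fmt == "tsv" else ",")
    if orientation == "samples-columns":
        X = X.T
        ids = [str(i + 1) for i in range(X.shape[0])]
    return X, ids


def read_labels(path) -> np.ndarray:
    """Load a label vector from a one- or two-column CSV (id,label)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"{path}: no such file")
    X, _, _ = _read_delimited(path, "\t" if path.suffix == ".tsv" else ",")
    return X[:, -1].astype(int)


def write_labels(path, ids, labels) -> None:
    pd.DataFrame({"id": ids, "label": np.asarray(labels, dtype=int)}).to_csv(
        path, index=False)


def write_projection(path, U) -> None:
    pd.DataFrame(np.asarray(U)).to_csv(path, index=False, header=False)


def input_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(path, config: dict, digest: str, seed: int,
                   timings: dict, warnings_seen: list) -> None:
    """Serialize the run manifest (config echo, input digest, versions)."""
    import scipy
    import sklearn

    manifest = {
        "config": config,
        "input_digest": digest,
        "seed": seed,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "timings_s": timings,
        "warnings": warnings_seen,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
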