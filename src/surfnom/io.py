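"""Plain-text readers and writers for the pipeline's tabular formats.

All on-disk formats are TSV (diff-able and language-agnostic):

* count matrix — first column ``feature_id``, remaining columns sample
  ids, integer cells; a MatrixMarket triplet file with two sidecar id
  files is accepted as an alternative,
* lengths — ``feature_id<TAB>length_bp``,
* design — ``sample_id<TAB>group``,
* tissue medians / any feature x column matrix — TSV with ``feature_id``
  first,
* candidate tables — TSV preceded by ``#``-prefixed metadata lines.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from ._validation import check_count_matrix
from .errors import SurfnomError, ValidationError


def read_counts(path) -> pd.DataFrame:
    """Read a count matrix from TSV, or from MTX if *path* ends in .mtx.

    The MTX route expects sidecar files ``<stem>.features.txt`` and
    ``<stem>.samples.txt`` next to the matrix, one id per line.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        return _read_counts_mtx(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index.name = "feature_id"
    return check_count_matrix(df.astype(int))


def _read_counts_mtx(path: Path) -> pd.DataFrame:
    from scipy.io import mmread

    feat_file = path.with_suffix("").with_suffix(".features.txt")
    samp_file = path.with_suffix("").with_suffix(".samples.txt")
    for f in (feat_file, samp_file):
        if not f.exists():
            raise SurfnomError(f"MTX sidecar file missing: {f}")
    mat = mmread(path).toarray()
    features = feat_file.read_text().split()
    samples = samp_file.read_text().split()
    if mat.shape != (len(features), len(samples)):
        raise ValidationError(
            f"MTX shape {mat.shape} does not match sidecar ids "
            f"({len(features)} x {len(samples)})"
        )
    df = pd.DataFrame(mat.astype(int), index=pd.Index(features, name="feature_id"),
                      columns=samples)
    return check_count_matrix(df)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("feature_id").to_csv(path, sep="\t")


def read_lengths(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[1] != 1:
        raise ValidationError(f"{path}: expected two columns feature_id, length_bp")
    s = df.iloc[:, 0].astype(int)
    s.index.name = "feature_id"
    s.name = "length_bp"
    return s


def write_lengths(lengths: pd.Series, path) -> None:
    lengths.rename("length_bp").rename_axis("feature_id").to_csv(path, sep="\t")


def read_design(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if df.shape[1] != 1:
        raise ValidationError(f"{path}: expected two columns sample_id, group")
    s = df.iloc[:, 0]
    s.index.name = "sample_id"
    s.name = "group"
    return s


def write_design(design: pd.Series, path) -> None:
    design.rename("group").rename_axis("sample_id").to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    """Feature x column real matrix (tissue medians, abundances, ...)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index.name = "feature_id"
    return df.astype(float)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis("feature_id").to_csv(path, sep="\t")


def read_tx2gene(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if df.shape[1] != 1:
        raise ValidationError(f"{path}: expected columns transcript_id, gene_id")
    s = df.iloc[:, 0]
    s.index.name = "transcript_id"
    s.name = "gene_id"
    return s


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a results table as TSV behind a ``#``-prefixed header block."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    """Inverse of :func:`write_table` (metadata lines are skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")
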