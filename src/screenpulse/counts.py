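"""Screen file I/O and control-based median-ratio count normalization.

Count tables are plain TSV with header ``sgRNA<TAB>gene<TAB><sample>...``
and libraries are plain CSV (see :mod:`screenpulse.library`).  The
normalization implemented here is the control-guide median-of-ratios
estimator: a per-sample size factor is the median, over non-targeting
control sgRNAs, of the ratio between the control's count in that sample
and its geometric mean across samples.  Controls containing a zero count
in any sample are excluded (their geometric mean is undefined); if every
control is excluded the estimator falls back to all all-positive sgRNAs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import FormatError, ConsistencyError, NormalizationError
from .library import CountMatrix, SgRNALibrary, parse_sample_name

__all__ = [
    "read_library", "read_counts", "write_counts",
    "size_factors_control", "design_from_samples",
    "read_design", "write_design",
]


def read_library(path) -> SgRNALibrary:
    return SgRNALibrary.from_csv(path)


def write_library(library: SgRNALibrary, path) -> None:
    library.to_csv(path)


def read_counts(path, library: SgRNALibrary | None = None,
                allow_unknown: bool = False) -> CountMatrix:
    """Read a count TSV; validates ids against ``library`` when given.

    Raises :class:`FormatError` with a 1-based line number on duplicate
    sgRNA ids, negative or non-integer counts, and (unless
    ``allow_unknown``) on sgRNAs absent from the library.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if list(df.columns[:2]) != ["sgRNA", "gene"]:
        raise FormatError(
            f"{path}: header must start with 'sgRNA<TAB>gene', got {list(df.columns[:2])}"
        )
    sample_cols = list(df.columns[2:])
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns")
    for name in sample_cols:
        parse_sample_name(name)

    dup = df["sgRNA"].duplicated()
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise FormatError(f"{path}:{i + 2}: duplicate sgRNA id {df['sgRNA'].iloc[i]!r}")

    vals = df[sample_cols].to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise FormatError(f"{path}: non-numeric count entries")
    bad = ~np.isfinite(vals) | (vals < 0) | (vals != np.floor(vals))
    if bad.any():
        i = int(np.flatnonzero(bad.any(axis=1))[0])
        raise FormatError(
            f"{path}:{i + 2}: negative or non-integer count for sgRNA "
            f"{df['sgRNA'].iloc[i]!r}"
        )

    if library is not None and not allow_unknown:
        unknown = set(df["sgRNA"]) - set(library.sgrna_ids)
        if unknown:
            raise ConsistencyError(
                f"{path}: sgRNA {sorted(unknown)[0]!r} not present in library "
                f"({len(unknown)} unknown rows total)"
            )

    counts = df.set_index("sgRNA")[sample_cols].astype(np.int64)
    genes = df.set_index("sgRNA")["gene"]
    return CountMatrix.from_samples(counts, genes=genes)


def write_counts(cm: CountMatrix, path) -> None:
    genes = cm.genes
    if genes is None:
        genes = pd.Series("NA", index=cm.counts.index)
    out = cm.counts.copy()
    out.insert(0, "gene", genes.reindex(cm.counts.index))
    out.index.name = "sgRNA"
    out.to_csv(path, sep="\t")


def size_factors_control(cm: CountMatrix, control_ids) -> pd.Series:
    """Median-of-ratios size factors anchored on control sgRNAs.

    For each control sgRNA *i* with all-positive counts, the geometric
    mean :math:`G_i` across samples is computed; the sample size factor is
    the median over those controls of :math:`K_{ir} / G_i`.
    """
    control_ids = list(control_ids)
    if not control_ids:
        raise NormalizationError("empty control set")
    missing = set(control_ids) - set(cm.counts.index)
    if missing:
        raise ConsistencyError(f"control sgRNA {sorted(missing)[0]!r} not in counts")

    def _factors(ids) -> pd.Series | None:
        sub = cm.counts.loc[ids].to_numpy(dtype=float)
        keep = (sub > 0).all(axis=1)
        if not keep.any():
            return None
        sub = sub[keep]
        logg = np.log(sub).mean(axis=1, keepdims=True)  # log geometric mean
        ratios = sub / np.exp(logg)
        return pd.Series(np.median(ratios, axis=0), index=cm.counts.columns)

    sf = _factors(control_ids)
    if sf is None:
        warnings.warn(
            "all control sgRNAs have a zero count in some sample; "
            "falling back to all-positive sgRNAs for size factors"
        )
        sf = _factors(list(cm.counts.index))
        if sf is None:
            raise NormalizationError(
                "no sgRNA with all-positive counts; cannot normalize"
            )
    return sf.astype(float)


# ---------------------------------------------------------------------------
# design matrices


def design_from_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """0/1 design matrix with one column per (condition, day) contrast.

    Baseline (``BASE``) samples get an all-zero row; every other sample
    gets a 1 in its ``{COND}_D{day}`` column.
    """
    conds = []
    for name, row in samples.iterrows():
        if row["condition"] == "BASE":
            continue
        conds.append((int(row["day"]), f"{row['condition']}_D{int(row['day'])}"))
    columns = [c for _, c in sorted(set(conds))]
    if not columns:
        raise ConsistencyError("no non-baseline samples; nothing to contrast")
    D = pd.DataFrame(0, index=samples.index, columns=columns, dtype=np.int8)
    for name, row in samples.iterrows():
        if row["condition"] != "BASE":
            D.loc[name, f"{row['condition']}_D{int(row['day'])}"] = 1
    if not (samples["condition"] == "BASE").any():
        raise ConsistencyError("design requires at least one baseline (Day 0) sample")
    return D


def write_design(design: pd.DataFrame, path) -> None:
    out = design.copy()
    out.insert(0, "baseline", (out.sum(axis=1) == 0).astype(int))
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    if "baseline" not in df.columns:
        raise FormatError(f"{path}: design TSV must have a 'baseline' column")
    D = df.drop(columns=["baseline"]).astype(np.int8)
    if ((D.sum(axis=1) > 1)).any():
        raise FormatError(f"{path}: a sample maps to more than one condition column")
    return D
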