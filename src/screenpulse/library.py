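"""In-memory containers for sgRNA libraries and count matrices.

A pooled screen is described by two tables: the *library* (which sgRNA
targets which gene, and whether it is a targeting guide, a non-targeting
control, or a positive control) and the *count matrix* (integer sgRNA ×
sample read counts plus per-sample metadata).  Samples follow the naming
convention ``REP{r}_{COND}_D{day}``; the shared baseline sample of each
replicate is ``REP{r}_BASE_D0``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError

#: recognised sgRNA classes
CLASSES = ("targeting", "nontargeting", "control")

#: gene id used for non-targeting control records
NTC_GENE = "NTC"

_SAMPLE_RE = re.compile(r"^REP(\d+)_([A-Za-z0-9]+)_D(\d+)$")


def parse_sample_name(name: str) -> tuple[int, str, int]:
    """Parse ``REP{r}_{COND}_D{day}`` into (replicate, condition, day)."""
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise FormatError(
            f"sample name {name!r} does not follow REP<r>_<COND>_D<day>"
        )
    return int(m.group(1)), m.group(2), int(m.group(3))


def sample_name(replicate: int, condition: str, day: int) -> str:
    return f"REP{replicate}_{condition}_D{day}"


@dataclass
class SgRNALibrary:
    """sgRNA → gene mapping with class labels and optional tiling annotations.

    ``table`` columns: ``sgRNA, gene, class, domain, cds_pos``.  ``domain``
    and ``cds_pos`` are only populated for tiling libraries.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sgRNA", "gene", "class"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FormatError(f"library table missing columns {missing}")
        if self.table["sgRNA"].duplicated().any():
            dup = self.table["sgRNA"][self.table["sgRNA"].duplicated()].iloc[0]
            raise FormatError(f"duplicate sgRNA id {dup!r} in library")
        bad = set(self.table["class"]) - set(CLASSES)
        if bad:
            raise FormatError(f"unknown sgRNA class values {sorted(bad)}")
        if (self.table["gene"].astype(str).str.len() == 0).any():
            raise FormatError("library contains records with empty gene id")
        for col in ("domain", "cds_pos"):
            if col not in self.table.columns:
                self.table[col] = pd.NA
        self.table = self.table.assign(
            domain=self.table["domain"].astype("string"),
            cds_pos=self.table["cds_pos"].astype("Int64"),
        ).reset_index(drop=True)

    # -- convenience views -------------------------------------------------
    @property
    def sgrna_ids(self) -> pd.Index:
        return pd.Index(self.table["sgRNA"])

    @property
    def ntc_ids(self) -> list[str]:
        return list(self.table.loc[self.table["class"] == "nontargeting", "sgRNA"])

    @property
    def control_ids(self) -> list[str]:
        return list(self.table.loc[self.table["class"] == "control", "sgRNA"])

    @property
    def targeting(self) -> pd.DataFrame:
        return self.table[self.table["class"] == "targeting"]

    @property
    def genes(self) -> list[str]:
        return sorted(self.targeting["gene"].unique())

    def gene_of(self) -> pd.Series:
        """Series mapping sgRNA id -> gene id."""
        return self.table.set_index("sgRNA")["gene"]

    def __len__(self) -> int:
        return len(self.table)

    # -- io ----------------------------------------------------------------
    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SgRNALibrary":
        try:
            table = pd.read_csv(path, dtype={"sgRNA": str, "gene": str})
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise FormatError(f"cannot parse library CSV {path}: {exc}") from exc
        if "cds_pos" in table.columns:
            table["cds_pos"] = table["cds_pos"].astype("Int64")
        return cls(table)


@dataclass
class CountMatrix:
    """Integer sgRNA × sample counts plus per-sample metadata.

    ``counts``: DataFrame indexed by sgRNA id, one column per sample.
    ``samples``: DataFrame indexed by sample name with columns
    ``condition`` (BASE for Day-0 baselines), ``day``, ``replicate``.
    ``genes``: Series mapping each count row to its gene id.
    ``size_factors``: optional per-sample positive scaling constants.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.Series | None = None
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.samples.index) != list(self.counts.columns):
            self.samples = self.samples.reindex(self.counts.columns)
        if self.samples[["condition", "day", "replicate"]].isna().any().any():
            raise ConsistencyError("sample metadata incomplete")
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise FormatError("negative counts")
        if self.size_factors is not None:
            sf = self.size_factors.reindex(self.counts.columns)
            if sf.isna().any() or (sf <= 0).any():
                raise ConsistencyError("size factors must be positive for every sample")
            self.size_factors = sf.astype(float)

    @classmethod
    def from_samples(cls, counts: pd.DataFrame, genes: pd.Series | None = None,
                     size_factors: pd.Series | None = None) -> "CountMatrix":
        """Build metadata by parsing the count-matrix column names."""
        meta = []
        for name in counts.columns:
            rep, cond, day = parse_sample_name(name)
            meta.append((name, cond, day, rep))
        samples = pd.DataFrame(
            meta, columns=["sample", "condition", "day", "replicate"]
        ).set_index("sample")
        return cls(counts=counts, samples=samples, genes=genes,
                   size_factors=size_factors)

    # -- views -------------------------------------------------------------
    @property
    def n_sgrna(self) -> int:
        return self.counts.shape[0]

    @property
    def sample_names(self) -> list[str]:
        return list(self.counts.columns)

    def replicates(self) -> list[int]:
        return sorted(self.samples["replicate"].unique())

    def subset_samples(self, names) -> "CountMatrix":
        names = list(names)
        sf = None if self.size_factors is None else self.size_factors.reindex(names)
        return CountMatrix(self.counts[names], self.samples.loc[names],
                           genes=self.genes, size_factors=sf)

    def normalized(self) -> pd.DataFrame:
        """Counts divided by size factors (raw counts are never overwritten)."""
        if self.size_factors is None:
            raise ConsistencyError("size factors not set; run size_factors_control first")
        return self.counts / self.size_factors

    def cpm(self) -> pd.DataFrame:
        """Counts-per-million depth normalization."""
        totals = self.counts.sum(axis=0).astype(float)
        if (totals <= 0).any():
            raise ConsistencyError("sample with zero total count")
        return self.counts / totals * 1e6
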