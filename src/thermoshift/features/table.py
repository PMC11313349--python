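"""The named-column numeric matrix passed between extractors and models."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class FeatureTable:
    """Numeric feature matrix keyed by record id.

    Wraps a :class:`pandas.DataFrame` (index = record ids, columns =
    feature names) plus per-column provenance (which extractor emitted
    the column and with what parameters).  Cells are never NaN: missing
    upstream resources cause the record to be dropped or imputed by
    explicit policy before a table is built.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        provenance: Mapping[str, Mapping] | None = None,
    ) -> None:
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature columns: {dups}")
        if df.isna().to_numpy().any():
            bad = df.columns[df.isna().any()].tolist()
            raise ValueError(f"NaN cells in columns {bad}")
        self.df = df.astype(float)
        self.df.index.name = "record_id"
        self.provenance: dict[str, dict] = {
            c: dict(provenance.get(c, {})) if provenance else {} for c in df.columns
        }

    # -- basic views -------------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def __len__(self) -> int:
        return len(self.df)

    def select(self, columns: Sequence[str]) -> "FeatureTable":
        missing = [c for c in columns if c not in self.df.columns]
        if missing:
            raise KeyError(f"columns not in table: {missing}")
        return FeatureTable(self.df[list(columns)], self.provenance)

    def subset_rows(self, ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.df.loc[list(ids)], self.provenance)

    # -- composition -------------------------------------------------------
    @staticmethod
    def concat(tables: Iterable["FeatureTable"]) -> "FeatureTable":
        """Horizontal concatenation; indices must agree, columns disjoint."""
        tables = list(tables)
        if not tables:
            raise ValueError("nothing to concatenate")
        base = tables[0]
        for t in tables[1:]:
            if not base.df.index.equals(t.df.index):
                raise ValueError("row keys differ between tables")
        df = pd.concat([t.df for t in tables], axis=1)
        prov: dict[str, dict] = {}
        for t in tables:
            prov.update(t.provenance)
        return FeatureTable(df, prov)

    @staticmethod
    def from_rows(
        rows: Mapping[str, Mapping[str, float]],
        provenance: Mapping[str, Mapping] | None = None,
    ) -> "FeatureTable":
        """Build from an ordered {record_id: {column: value}} mapping."""
        df = pd.DataFrame.from_dict(rows, orient="index")
        return FeatureTable(df, provenance)

    # -- persistence -------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as TSV with a JSON provenance sidecar."""
        path = Path(path)
        self.df.to_csv(path, sep="\t")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(self.provenance, indent=1, sort_keys=True))

    @staticmethod
    def from_tsv(path: str | Path) -> "FeatureTable":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        sidecar = path.with_suffix(path.suffix + ".json")
        prov = json.loads(sidecar.read_text()) if sidecar.exists() else None
        return FeatureTable(df, prov)

    def content_hash(self) -> str:
        """Stable hash of ids, columns and cell values (purity checks)."""
        h = hashlib.sha256()
        h.update("\x00".join(map(str, self.df.index)).encode())
        h.update("\x00".join(map(str, self.df.columns)).encode())
        h.update(np.ascontiguousarray(self.df.to_numpy()).tobytes())
        return h.hexdigest()
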