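"""Light tabular containers shared by the estimator and downstream stages.

Flux matrices (sample x module) and balance profiles (sample x
intermediate) are plain :class:`pandas.DataFrame` objects; only the
expression matrix gets a wrapper because it bundles per-sample metadata
with the gene x sample value table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DimensionError, InputError


@dataclass
class ExpressionMatrix:
    """Gene x sample expression on the log(FPKM+1) scale.

    ``values`` has genes as rows and samples as columns; ``metadata`` (optional)
    is indexed by sample id and typically carries ``cancer_type``, ``status``
    (tumor/normal) and ``stage`` columns.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.values.columns.is_unique:
            raise InputError("sample ids must be unique")
        if not self.values.index.is_unique:
            raise InputError("gene ids must be unique")
        arr = self.values.to_numpy()
        if np.issubdtype(arr.dtype, np.number) and np.nanmin(arr, initial=0.0) < 0:
            raise InputError("expression values must be non-negative (log(FPKM+1) scale)")
        if self.metadata is not None:
            missing = self.values.columns.difference(self.metadata.index)
            if len(missing):
                raise DimensionError(f"metadata missing samples: {list(missing)[:5]} ...")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, values_path: str | Path, metadata_path: str | Path | None = None) -> None:
        self.values.to_csv(values_path, sep="\t", float_format="%.6g")
        if metadata_path is not None and self.metadata is not None:
            self.metadata.to_csv(metadata_path, sep="\t")

    @classmethod
    def from_tsv(
        cls, values_path: str | Path, metadata_path: str | Path | None = None
    ) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        metadata = (
            pd.read_csv(metadata_path, sep="\t", index_col=0) if metadata_path else None
        )
        return cls(values, metadata)


def as_expression(data) -> ExpressionMatrix:
    """Coerce an :class:`ExpressionMatrix` or a genes-as-rows DataFrame."""
    if isinstance(data, ExpressionMatrix):
        return data
    if isinstance(data, pd.DataFrame):
        return ExpressionMatrix(data)
    raise InputError(f"expected ExpressionMatrix or DataFrame, got {type(data).__name__}")
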