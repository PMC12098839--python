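"""Protein roll-up, channel normalization, log2 transform.

Retained PSMs are summed to proteins per channel on the S/N scale
(summation commutes through the peptide level, so PSM->protein directly
equals PSM->peptide->protein).  Channels are then rescaled so each
column's total equals the mean of the original column totals — the
equal-loading normalization appropriate for a single-batch 18-plex
design — and log2-transformed for linear modeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from plexquant.extraction import PsmQuantRecord
from plexquant.reference import channel_labels

__all__ = [
    "ProteinQuantMatrix",
    "rollup_proteins",
    "normalize_channels",
    "log2_matrix",
    "read_design_table",
]


@dataclass
class ProteinQuantMatrix:
    """Proteins x channels matrix of summed reporter S/N.

    ``values`` is a DataFrame indexed by protein id with one column per
    channel label.  ``annotations`` optionally maps channels to samples
    (age, sex, tissue, replicate).  ``normalized`` records whether the
    equal-loading normalization ran; ``log2`` whether values are on the
    log2 scale.
    """

    values: pd.DataFrame
    annotations: Optional[pd.DataFrame] = None
    normalized: bool = False
    log2: bool = False
    dropped_proteins: tuple[str, ...] = field(default_factory=tuple)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def channels(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="protein")

    @classmethod
    def from_tsv(cls, path, design: Optional[pd.DataFrame] = None,
                 normalized: bool = False, log2: bool = False) -> "ProteinQuantMatrix":
        values = pd.read_csv(path, sep="\t", index_col="protein")
        return cls(values=values, annotations=design,
                   normalized=normalized, log2=log2)


def rollup_proteins(
    records: Sequence[PsmQuantRecord],
    protein_map: Optional[Mapping[str, Sequence[str]]] = None,
    annotations: Optional[pd.DataFrame] = None,
) -> ProteinQuantMatrix:
    """Sum retained PSMs' per-channel S/N to proteins.

    ``protein_map`` (psm_id -> protein ids) overrides the protein ids
    carried on the records; by default each record contributes to every
    protein listed on it (shared peptides are assumed resolved upstream
    by parsimony; a multi-protein PSM triggers a warning).  Proteins
    with no retained PSMs simply do not appear.
    """
    labels = list(channel_labels())
    if not records:
        warnings.warn("rollup_proteins: no retained PSMs; empty matrix")
        empty = pd.DataFrame(columns=labels, dtype=float)
        empty.index.name = "protein"
        return ProteinQuantMatrix(values=empty, annotations=annotations)

    sums: dict[str, np.ndarray] = {}
    shared = 0
    for rec in records:
        proteins = (
            tuple(protein_map[rec.psm_id])
            if protein_map is not None
            else rec.protein_ids
        )
        if len(proteins) > 1:
            shared += 1
        sn = np.asarray(rec.sn_vector(), dtype=float)
        for prot in proteins:
            if prot in sums:
                sums[prot] += sn
            else:
                sums[prot] = sn.copy()
    if shared:
        warnings.warn(
            f"{shared} PSM(s) mapped to multiple proteins; "
            "each contributes to every listed protein"
        )
    values = pd.DataFrame.from_dict(sums, orient="index", columns=labels)
    values.index.name = "protein"
    return ProteinQuantMatrix(values=values, annotations=annotations)


def normalize_channels(matrix: ProteinQuantMatrix) -> ProteinQuantMatrix:
    """Equal-loading normalization: rescale each channel so all column
    totals equal the mean of the original totals.

    Within-channel ratios between proteins are preserved exactly.  A
    zero-total channel cannot be rescaled and raises.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    if matrix.log2:
        raise ValueError("normalize before log2 transform, not after")
    totals = matrix.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"cannot normalize zero-total channel(s): {', '.join(zero.index)}"
        )
    target = totals.mean()
    scaled = matrix.values * (target / totals)
    return replace(matrix, values=scaled, normalized=True)


def log2_matrix(matrix: ProteinQuantMatrix, pseudo: float = 0.0) -> ProteinQuantMatrix:
    """log2(value + pseudo) transform of a normalized matrix.

    Zeros are only admissible with ``pseudo > 0``; otherwise the
    offending cells are listed in the error.
    """
    if pseudo < 0:
        raise ValueError("pseudo-count must be >= 0")
    if matrix.log2:
        raise ValueError("matrix is already log2-transformed")
    if pseudo == 0:
        bad = matrix.values <= 0
        if bad.any().any():
            cells = [
                f"({prot}, {chan})"
                for prot, row in bad.iterrows()
                for chan, flag in row.items()
                if flag
            ]
            shown = ", ".join(cells[:10]) + ("..." if len(cells) > 10 else "")
            raise ValueError(
                f"non-positive values with pseudo=0 at cells: {shown}"
            )
    transformed = np.log2(matrix.values + pseudo)
    return replace(matrix, values=transformed, log2=True)


def read_design_table(path) -> pd.DataFrame:
    """Read a sample design TSV: channel, age_months, sex, tissue, replicate."""
    design = pd.read_csv(path, sep="\t", dtype={"channel": str})
    required = {"channel", "age_months", "sex"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing column(s): {sorted(missing)}")
    return design
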