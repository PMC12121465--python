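"""SILAC proteome assembly: quantification filtering and labeling efficiency.

A SILAC screen mixes each circadian sample 1:1 with a heavy-labeled
reference, so each feature carries one heavy/light ratio per (timepoint,
replicate).  Identification is upstream of this module; here the identified
table is reduced to the *quantified* proteome by requiring every timepoint
to be supported by at least two replicate ratios, after which ratios are
log2-transformed for the rhythm analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rhythms import OmicsTimeTable, _COLUMN_RE


class RawSilacTable:
    """Feature x (timepoint x replicate) table of raw (positive) SILAC ratios.

    Uses the same ``CT{t}_rep{r}`` column dialect as
    :class:`~clockworks.rhythms.OmicsTimeTable`; empty cells are missing.
    """

    def __init__(self, ratios: pd.DataFrame):
        for col in ratios.columns:
            if not _COLUMN_RE.match(str(col)):
                raise ValueError(f"column {col!r} does not match 'CT<t>_rep<r>'")
        self.ratios = ratios.astype(float)
        self._groups: dict[float, list[str]] = {}
        for col in ratios.columns:
            m = _COLUMN_RE.match(str(col))
            self._groups.setdefault(float(m["ct"]), []).append(col)

    @property
    def feature_ids(self) -> pd.Index:
        return self.ratios.index

    @classmethod
    def from_tsv(cls, path) -> "RawSilacTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.ratios.to_csv(path, sep="\t", na_rep="")


def assemble_quantified(
    raw: RawSilacTable, min_ratios_per_timepoint: int = 2
) -> tuple[OmicsTimeTable, dict[str, int]]:
    """Apply the quantification filter and log2-transform retained ratios.

    A feature is retained iff *every* timepoint has at least
    ``min_ratios_per_timepoint`` non-missing replicate ratios; the retention
    decision depends only on the missingness mask.  Returns the quantified
    log2 table and a report with identified / quantified / excluded counts.
    """
    vals = raw.ratios
    bad = (vals <= 0) & vals.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-positive ratio at feature {vals.index[r]!r}, column {vals.columns[c]!r}"
        )
    keep = pd.Series(True, index=vals.index)
    for _, cols in sorted(raw._groups.items()):
        keep &= vals[cols].notna().sum(axis=1) >= min_ratios_per_timepoint
    quantified = np.log2(vals.loc[keep])
    report = {
        "n_identified": int(len(vals)),
        "n_quantified": int(keep.sum()),
        "n_excluded": int((~keep).sum()),
    }
    return OmicsTimeTable(quantified), report


@dataclass
class LabelingEfficiency:
    """Isotope incorporation summary from heavy/light peptide counts.

    ``fraction`` is heavy / (heavy + light), the incorporation bounded by 1;
    ``heavy_to_light`` is the literal heavy / light count ratio.
    """

    fraction: float
    heavy_to_light: float


def labeling_efficiency(n_heavy: int, n_light: int) -> LabelingEfficiency:
    """Labeling efficiency from heavy and light peptide counts."""
    if n_heavy < 0 or n_light < 0:
        raise ValueError("peptide counts must be non-negative")
    if n_heavy + n_light == 0:
        raise ValueError("at least one peptide count must be positive")
    frac = n_heavy / (n_heavy + n_light)
    ratio = n_heavy / n_light if n_light > 0 else float("inf")
    return LabelingEfficiency(fraction=frac, heavy_to_light=ratio)
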