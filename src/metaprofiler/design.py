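"""Design sheets: which alignment file plays which role in which experiment.

The sheet is a delimited table whose first column (header literally
``sample``) lists alignment-file paths and whose remaining columns are named
experiments. Cells hold a role code: 0 = unused, 1 = ChIP, 2 = control — the
historical convention of design objects in metagene-style analyses. One file
can serve different roles across experiments (a shared input control, say).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignments import CoverageTrack, RLEVector

log = logging.getLogger(__name__)

UNUSED, CHIP, CONTROL = 0, 1, 2


class DesignError(ValueError):
    """Raised for a structurally invalid design sheet."""


@dataclass
class DesignSheet:
    samples: list[str]
    codes: pd.DataFrame  # index: sample path, columns: experiment names
    no_control: list[str] = field(default_factory=list)  # experiments lacking a control

    @property
    def experiments(self) -> list[str]:
        return list(self.codes.columns)

    def chip_files(self, experiment: str) -> list[str]:
        col = self.codes[experiment]
        return list(col.index[col == CHIP])

    def control_files(self, experiment: str) -> list[str]:
        col = self.codes[experiment]
        return list(col.index[col == CONTROL])


def parse_design(path) -> DesignSheet:
    """Parse and validate a TSV/CSV design sheet.

    The delimiter is chosen from the extension (``.csv`` -> comma, otherwise
    tab). Every experiment must have at least one ChIP sample; experiments
    without a control are allowed but flagged (background removal is skipped
    for them downstream, with a warning).
    """
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise DesignError(f"{path}: need a 'sample' column plus >=1 experiment column")
    if df.columns[0] != "sample":
        raise DesignError(f"{path}: first column header must be 'sample', got {df.columns[0]!r}")
    samples = df.iloc[:, 0].astype(str).tolist()
    if len(set(samples)) != len(samples):
        raise DesignError(f"{path}: duplicate sample paths in design sheet")
    codes = df.set_index(df.columns[0]).apply(pd.to_numeric, errors="coerce")
    if codes.isna().any().any():
        raise DesignError(f"{path}: non-numeric role codes")
    codes = codes.astype(int)
    bad = ~codes.isin((UNUSED, CHIP, CONTROL))
    if bad.any().any():
        raise DesignError(f"{path}: role codes must be 0 (unused), 1 (ChIP) or 2 (control)")
    no_control = []
    for exp in codes.columns:
        col = codes[exp]
        if (col == CHIP).sum() == 0:
            raise DesignError(f"{path}: experiment {exp!r} has no ChIP sample")
        if (col == CONTROL).sum() == 0:
            no_control.append(exp)
            log.warning(
                "experiment %r has no control; background removal will be skipped", exp
            )
    return DesignSheet(samples=samples, codes=codes, no_control=no_control)


def merge_replicates(tracks: list[CoverageTrack], sample_id: str | None = None) -> CoverageTrack:
    """Pool replicate tracks by summing raw per-base counts.

    Library sizes add. Pooling happens on counts, before any normalisation,
    so one curve summarises all replicates of a factor.
    """
    if not tracks:
        raise ValueError("merge_replicates needs at least one track")
    if len(tracks) == 1:
        return tracks[0]
    n_regions = {len(t.vectors) for t in tracks}
    if len(n_regions) != 1:
        raise ValueError("tracks cover different numbers of regions")
    widths = {len(v) for t in tracks for v in t.vectors}
    if len(widths) > 1:
        raise ValueError(f"mismatched region widths across tracks: {sorted(widths)}")
    merged = CoverageTrack(
        sample_id=sample_id or "+".join(t.sample_id for t in tracks),
        library_size=sum(t.library_size for t in tracks),
    )
    for i in range(n_regions.pop()):
        total = np.sum([t.dense(i) for t in tracks], axis=0)
        merged.vectors.append(RLEVector.encode(total))
    return merged
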