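"""Entity-level expression summarization from probe-level intensities.

The global signal of an entity in one sample is the log2 of the
arithmetic mean of its member probes' linear-scale intensities
(``scale="linear-mean"``, the default). A mean-of-logs alternative
(``scale="log-mean"``) is provided as the common-practice variant. Means
are floored (default 1.0) before the log to keep all-zero probe vectors
finite.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .sets import ProbesetDefinition

logger = logging.getLogger(__name__)

SCALE_LINEAR_MEAN = "linear-mean"
SCALE_LOG_MEAN = "log-mean"


class SummarizeError(Exception):
    pass


def read_intensity_tsv(path: str) -> pd.DataFrame:
    """Probe × sample intensity matrix: first column probe ids, header
    row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    if df.index.has_duplicates:
        raise SummarizeError(f"{path}: duplicate probe ids")
    return df


def write_signal_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index_label="entity_id", float_format="%.6g")


def summarize(matrix: pd.DataFrame,
              sets: Sequence[ProbesetDefinition],
              scale: str = SCALE_LINEAR_MEAN,
              floor: float = 1.0) -> pd.DataFrame:
    """Summarize probe intensities to one signal per entity and sample.

    Probes referenced by a set but absent from the matrix are dropped
    with a warning; entities left with no probes are omitted from the
    output.
    """
    if (matrix.values < 0).any():
        raise SummarizeError("negative intensities in input matrix")
    if scale not in (SCALE_LINEAR_MEAN, SCALE_LOG_MEAN):
        raise SummarizeError(f"unknown scale {scale!r}")
    rows = {}
    for s in sets:
        # canonical probe order makes the float reduction, and hence the
        # output, invariant under probe-list permutations
        present = sorted(p for p in s.probe_ids if p in matrix.index)
        missing = len(s.probe_ids) - len(present)
        if missing:
            logger.warning("entity %s: %d probe(s) absent from the matrix",
                           s.entity_id, missing)
        if not present:
            continue
        sub = matrix.loc[present].to_numpy(dtype=float)
        if scale == SCALE_LINEAR_MEAN:
            mean = sub.mean(axis=0)
            clipped = np.maximum(mean, floor)
            if (mean < floor).any():
                logger.warning("entity %s: mean intensity below floor %g "
                               "clipped", s.entity_id, floor)
            rows[s.entity_id] = np.log2(clipped)
        else:
            rows[s.entity_id] = np.log2(np.maximum(sub, floor)).mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=matrix.columns).sort_index()


def probe_profile(matrix: pd.DataFrame, probe_ids: Sequence[str],
                  sample_order: Optional[Sequence[str]] = None
                  ) -> pd.DataFrame:
    """Raw per-probe intensity rows in the requested sample order."""
    if sample_order is None:
        sample_order = list(matrix.columns)
    missing = [p for p in probe_ids if p not in matrix.index]
    if missing:
        raise SummarizeError(f"unknown probe id(s): {missing}")
    bad_samples = [s for s in sample_order if s not in matrix.columns]
    if bad_samples:
        raise SummarizeError(f"unknown sample id(s): {bad_samples}")
    return matrix.loc[list(probe_ids), list(sample_order)]
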