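"""Canonical 43-region node set and its reference network labeling.

The analysis operates on 43 task-defined regions of interest grouped into
three large-scale networks: the default-mode network (DN, 16 regions), the
frontoparietal control network (CN, 14) and the dorsal attention network
(AN, 13).  The shipped labeling uses the standard anatomical abbreviations
(amPFC, pCC, STS, ...) with an ``L.``/``R.`` laterality prefix.  The
laterality expansion from the 25 base anatomical names to 43 lateralized
labels is a constructed convention of this package (the original task-based
node coordinates are not redistributed here); no computation depends on it
beyond the block sizes and the name-keyed ordering.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

NETWORKS: tuple[str, ...] = ("DN", "CN", "AN")

#: Unordered network pairs in canonical order, used for between-network summaries.
NETWORK_PAIRS: tuple[tuple[str, str], ...] = (("DN", "CN"), ("DN", "AN"), ("CN", "AN"))

REFERENCE_SIZES: dict[str, int] = {"DN": 16, "CN": 14, "AN": 13}


def _load_reference_table() -> pd.DataFrame:
    with resources.files("reliafc.data").joinpath("reference_partition.csv").open() as fh:
        table = pd.read_csv(fh)
    return table


_TABLE = _load_reference_table()

#: Canonical region ordering used throughout the package (index 0..42).
REGION_NAMES: tuple[str, ...] = tuple(_TABLE["region"])

#: region name -> reference network label (DN/CN/AN).
REFERENCE_LABELS: dict[str, str] = dict(zip(_TABLE["region"], _TABLE["network"]))

N_REGIONS: int = len(REGION_NAMES)
N_EDGES: int = N_REGIONS * (N_REGIONS - 1) // 2  # 903 unordered pairs


def region_index(name: str) -> int:
    """Return the canonical 0-based index of a region name."""
    try:
        return REGION_NAMES.index(name)
    except ValueError:
        raise KeyError(f"unknown region name: {name!r}") from None
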