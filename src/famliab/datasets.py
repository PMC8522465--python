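"""Bundled aggregate data and count-file IO.

``swedish_iim_pair_counts.csv`` holds the published aggregate pair counts of
idiopathic inflammatory myopathy among first-degree relatives of Swedish
register cases (1997-2016) and their matched comparators — exposed/total by
kinship, with ``ge1_relative`` counting index persons with at least one
affected relative.  These published margins are enough to reproduce the
headline crude odds ratios and heritability estimates without any microdata.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["load_counts_file", "published_pair_counts", "PUBLISHED_COUNTS_NAME"]

PUBLISHED_COUNTS_NAME = "swedish_iim_pair_counts.csv"

_REQUIRED = ["kinship", "group", "exposed", "total"]


def load_counts_file(path: str | Path) -> dict[str, dict[str, tuple[int, int]]]:
    """Parse a pair-count CSV into ``{kinship: {group: (exposed, total)}}``.

    The file must have columns ``kinship, group, exposed, total`` with
    ``group`` in {case, comparator}.  Malformed rows raise with their line
    number; an empty file is an error.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no count rows")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out: dict[str, dict[str, tuple[int, int]]] = {}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            exposed = int(row["exposed"])
            total = int(row["total"])
        except (TypeError, ValueError) as e:
            raise ValueError(f"{path}:{line}: non-integer counts") from e
        if row["group"] not in ("case", "comparator"):
            raise ValueError(
                f"{path}:{line}: group must be 'case' or 'comparator', "
                f"got {row['group']!r}"
            )
        if exposed < 0 or total < 0 or exposed > total:
            raise ValueError(
                f"{path}:{line}: need 0 <= exposed <= total, "
                f"got {exposed}/{total}"
            )
        out.setdefault(str(row["kinship"]), {})[str(row["group"])] = (
            exposed, total,
        )
    return out


def published_pair_counts() -> dict[str, dict[str, tuple[int, int]]]:
    """The bundled published Swedish IIM pair counts."""
    with resources.as_file(
        resources.files("famliab.data") / PUBLISHED_COUNTS_NAME
    ) as p:
        return load_counts_file(p)
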