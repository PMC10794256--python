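"""Domain-frequency composition summaries per BGC class and role.

Domain frequency N means the domain appears N times on average within a
BGC of the group; groups are (bgc_class, role) pairs so candidate and
reference compositions can be compared side by side.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import pandas as pd

from .bgc_io import BGCRecord

__all__ = ["domain_frequencies", "top_domains"]


def domain_frequencies(
    records: Sequence[BGCRecord], complete_only: bool = False
) -> pd.DataFrame:
    """Mean per-BGC domain counts grouped by (bgc_class, role).

    frequency(d) = total count of d in the group / number of BGCs in the
    group; domains never seen in a group are omitted (implicit zero).
    Contig-edge records are included unless ``complete_only`` is set.
    """
    pool = [r for r in records if not (complete_only and r.contig_edge)]
    if not pool:
        raise ValueError("no records to summarise (empty group)")
    rows = []
    groups: dict[tuple[str, str], list[BGCRecord]] = {}
    for r in pool:
        groups.setdefault((r.bgc_class, r.role), []).append(r)
    for (cls, role), members in sorted(groups.items()):
        counts: Counter[str] = Counter()
        for r in members:
            counts.update(d.label for d in r.domains)
        n = len(members)
        for label in sorted(counts):
            rows.append((cls, role, label, counts[label] / n, n))
    return pd.DataFrame(
        rows, columns=["bgc_class", "role", "domain", "frequency", "n_bgcs"]
    )


def top_domains(table: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k highest-frequency domains per (bgc_class, role) group.

    Ties at rank k are broken lexicographically by domain label.
    """
    if table.empty:
        raise ValueError("empty composition table")
    ordered = table.sort_values(
        ["bgc_class", "role", "frequency", "domain"],
        ascending=[True, True, False, True],
    )
    out = ordered.groupby(["bgc_class", "role"], sort=True).head(k)
    out = out.reset_index(drop=True)
    out["rank"] = out.groupby(["bgc_class", "role"]).cumcount() + 1
    return out
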