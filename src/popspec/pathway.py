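"""Denitrification-pathway completeness from per-genome gene flags.

complete = (napA or narG) and (nirS or nirK) and norB and nosZ;
none = all six genes absent; everything else is partial.
"""

from __future__ import annotations

from collections import Counter

import pandas as pd

__all__ = ["GENES", "classify_pathway", "summarize_pathway_counts"]

GENES = ("napA", "narG", "nirS", "nirK", "norB", "nosZ")


def classify_pathway(profile: dict[str, bool]) -> str:
    missing = [g for g in GENES if g not in profile]
    if missing:
        raise ValueError(f"missing gene flags: {missing}")
    flags = {g: bool(profile[g]) for g in GENES}
    if not any(flags.values()):
        return "none"
    complete = (
        (flags["napA"] or flags["narG"])
        and (flags["nirS"] or flags["nirK"])
        and flags["norB"]
        and flags["nosZ"]
    )
    return "complete" if complete else "partial"


def summarize_pathway_counts(profiles: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions of complete/partial/none over genome rows."""
    if profiles.empty:
        raise ValueError("no profiles given")
    classes = Counter(
        classify_pathway(row.to_dict()) for _, row in profiles.astype(bool).iterrows()
    )
    total = sum(classes.values())
    rows = [
        {"class": c, "count": classes.get(c, 0), "fraction": classes.get(c, 0) / total}
        for c in ("complete", "partial", "none")
    ]
    return pd.DataFrame(rows)
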