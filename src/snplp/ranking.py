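"""Shared ranked-list container used by every SNP ranker."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass
class RankedEntry:
    snp_id: str
    snp_score: float
    state_scores: dict[int, float]
    rank: int  # 1-based


@dataclass
class RankedList:
    """Ordered SNP ranking with per-SNP scores.

    Entries are sorted by descending ``snp_score``; ties are broken by
    lexicographic ``snp_id`` so rankings are deterministic across
    platforms.  ``method`` names the ranker that produced the list.
    """

    entries: list[RankedEntry]
    method: str = ""
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def snp_ids(self) -> list[str]:
        return [e.snp_id for e in self.entries]

    def top(self, n: int) -> list[str]:
        """Identifiers of the top-n SNPs."""
        if n < 1:
            raise ValueError("depth must be >= 1")
        return [e.snp_id for e in self.entries[:n]]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "rank": e.rank,
                "snp_id": e.snp_id,
                "snp_score": e.snp_score,
                "score_state0": e.state_scores.get(0, 0.0),
                "score_state1": e.state_scores.get(1, 0.0),
                "score_state2": e.state_scores.get(2, 0.0),
                "method": self.method,
            }
            for e in self.entries
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def make_ranked_list(
    scores: dict[str, float],
    state_scores: dict[str, dict[int, float]] | None = None,
    method: str = "",
    params: dict | None = None,
) -> RankedList:
    """Build a RankedList from per-SNP scores (higher = more associated).

    Sort is by descending score then ascending snp_id.
    """
    order = sorted(scores, key=lambda s: (-scores[s], s))
    entries = [
        RankedEntry(
            snp_id=s,
            snp_score=float(scores[s]),
            state_scores=dict((state_scores or {}).get(s, {})),
            rank=i + 1,
        )
        for i, s in enumerate(order)
    ]
    return RankedList(entries=entries, method=method, params=dict(params or {}))
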