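"""Per-concept agreement/disagreement frequencies and contestedness.

For each time window the table records, per concept, how many statements
agreed and disagreed, how prominent the concept was (total), and how
contested it was.  Contestedness is min(n_agree, n_disagree) /
max(n_agree, n_disagree): 1 for perfectly divided opinion, 0 for unanimity.
(The source analyses describe contested concepts qualitatively; the min/max
ratio is an artifact-defined statistic that reproduces their ranking.)
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass

import pandas as pd

from discoursenet.statement_store import AGREE, Corpus, slice_window

try:  # plotting is optional output; the table is canonical
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
except ImportError:  # pragma: no cover
    plt = None


def contestedness(n_agree: int, n_disagree: int) -> float:
    """min/max ratio of the two stance counts.

    Symmetric in its arguments and invariant under scaling both counts;
    undefined (ValueError) when both are zero.
    """
    if n_agree < 0 or n_disagree < 0:
        raise ValueError("counts must be non-negative")
    if n_agree + n_disagree == 0:
        raise ValueError("contestedness undefined for zero statements")
    return min(n_agree, n_disagree) / max(n_agree, n_disagree)


@dataclass
class ConceptFrequencyTable:
    """Per-concept stance counts for one window, sorted by prominence.

    ``rows`` columns: concept, n_agree, n_disagree, total, contestedness;
    sorted by total descending, ties broken lexicographically by concept.
    """

    window: tuple[dt.date, dt.date] | None
    rows: pd.DataFrame

    def __len__(self) -> int:
        return len(self.rows)


def concept_frequency(corpus: Corpus) -> ConceptFrequencyTable:
    """Statement-level tallies per concept and stance (an empty corpus yields
    an empty table, not an error)."""
    counts: dict[str, list[int]] = {}
    for s in corpus.statements:
        row = counts.setdefault(s.concept, [0, 0])
        row[0 if s.stance == AGREE else 1] += 1
    records = []
    for concept, (na, nd) in counts.items():
        records.append(
            {
                "concept": concept,
                "n_agree": na,
                "n_disagree": nd,
                "total": na + nd,
                "contestedness": contestedness(na, nd),
            }
        )
    df = pd.DataFrame.from_records(
        records, columns=["concept", "n_agree", "n_disagree", "total", "contestedness"]
    )
    if len(df):
        df = df.sort_values(
            ["total", "concept"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return ConceptFrequencyTable(corpus.window, df)


def windowed_concept_frequency(
    corpus: Corpus, windows: list[tuple[dt.date, dt.date]]
) -> list[ConceptFrequencyTable]:
    return [concept_frequency(slice_window(corpus, start, end)) for start, end in windows]


def write_concept_csv(tables: list[ConceptFrequencyTable], path) -> None:
    """One CSV for all windows: window_start,window_end,concept,n_agree,
    n_disagree,total,contestedness."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["window_start", "window_end", "concept", "n_agree", "n_disagree", "total", "contestedness"]
        )
        for table in tables:
            start, end = table.window if table.window else ("", "")
            for rec in table.rows.itertuples(index=False):
                writer.writerow(
                    [start, end, rec.concept, rec.n_agree, rec.n_disagree, rec.total,
                     f"{rec.contestedness:.6f}"]
                )


def plot_concept_frequency(table: ConceptFrequencyTable, path, top: int = 20) -> None:
    """Horizontal bar plot of the most prominent concepts (agree right,
    disagree left), one file per window."""
    if plt is None:  # pragma: no cover
        raise RuntimeError("matplotlib is not available")
    df = table.rows.head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(8, max(2, 0.35 * len(df))))
    ax.barh(df["concept"], df["n_agree"], color="#2166ac", label="agree")
    ax.barh(df["concept"], -df["n_disagree"], color="#b2182b", label="disagree")
    ax.axvline(0, color="black", linewidth=0.8)
    ax.set_xlabel("statements")
    if table.window:
        ax.set_title(f"{table.window[0]} to {table.window[1]}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
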