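"""Table-style report of selection estimates across years.

The layout groups rows into (a) total selection on leaf-out day, (b) total
selection on first flowering day and (c) direct selection (gradients from
the multi-trait linear model, squared and interaction terms from the full
model), with estimate / lower / upper columns per year.  Significant
estimates (BCa interval excluding zero) are marked with ``*`` in the text
rendering; the CSV carries an explicit ``significant`` column.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .selection import INTERACTION_TERM, SelectionTable

__all__ = ["render_table1", "selection_tables_frame"]

_SECTIONS = [
    (
        "(a) Total selection: leaf-out day",
        "total_leafout",
        ["leaf_out_day", "plant_size", "leaf_out_day^2"],
    ),
    (
        "(b) Total selection: first flowering day",
        "total_ffd",
        ["first_flowering_day", "plant_size", "first_flowering_day^2"],
    ),
    (
        "(c) Direct selection",
        None,  # assembled from direct_linear + direct_full
        [
            ("direct_linear", "leaf_out_day"),
            ("direct_linear", "first_flowering_day"),
            ("direct_linear", "plant_size"),
            ("direct_full", "leaf_out_day^2"),
            ("direct_full", "first_flowering_day^2"),
            ("direct_full", INTERACTION_TERM),
        ],
    ),
]


def selection_tables_frame(tables: list[SelectionTable]) -> pd.DataFrame:
    """Concatenate selection tables into one long-format frame."""
    if not tables:
        raise ValueError("no selection tables to report")
    return pd.concat([t.to_frame() for t in tables], ignore_index=True)


def _lookup(tables: list[SelectionTable], family: str, year) -> SelectionTable | None:
    for t in tables:
        if t.family == family and t.year == year:
            return t
    return None


def render_table1(tables: list[SelectionTable]) -> tuple[pd.DataFrame, str]:
    """Build the grouped selection report.

    Returns ``(frame, text)``: a wide CSV-ready frame with one row per
    (section, term) and estimate/lower/upper/significant columns per year,
    plus a fixed-width text rendering with ``*`` marking significance.
    Missing model families produce NA rows and a warning.
    """
    if not tables:
        raise ValueError("no selection tables to report")
    years = sorted({t.year for t in tables}, key=str)
    schemes = {t.scheme for t in tables}
    if len(schemes) > 1:
        raise ValueError(f"render_table1 expects one scheme per call, got {sorted(schemes)}")

    rows = []
    for section, family, terms in _SECTIONS:
        for spec in terms:
            fam, term = spec if isinstance(spec, tuple) else (family, spec)
            row: dict = {"section": section, "term": term}
            for year in years:
                table = _lookup(tables, fam, year)
                est = None
                if table is not None:
                    try:
                        est = table[term]
                    except KeyError:
                        est = None
                if est is None:
                    warnings.warn(
                        f"missing estimate for family {fam!r}, term {term!r}, "
                        f"year {year!r}; emitting NA",
                        UserWarning,
                        stacklevel=2,
                    )
                    row[f"estimate_{year}"] = np.nan
                    row[f"lower_{year}"] = np.nan
                    row[f"upper_{year}"] = np.nan
                    row[f"significant_{year}"] = pd.NA
                else:
                    row[f"estimate_{year}"] = est.estimate
                    row[f"lower_{year}"] = est.bca_lower
                    row[f"upper_{year}"] = est.bca_upper
                    row[f"significant_{year}"] = est.significant
            rows.append(row)
    frame = pd.DataFrame(rows)

    lines = []
    header = f"{'':44s}" + "".join(f"{str(y):>30s}" for y in years)
    sub = f"{'term':44s}" + "".join(f"{'estimate':>12s}{'lower':>9s}{'upper':>9s}" for _ in years)
    lines += [header, sub, "-" * len(sub)]
    current_section = None
    for _, row in frame.iterrows():
        if row["section"] != current_section:
            current_section = row["section"]
            lines.append(current_section)
        cells = f"  {row['term']:<42s}"
        for year in years:
            est = row[f"estimate_{year}"]
            lo = row[f"lower_{year}"]
            hi = row[f"upper_{year}"]
            sig = row[f"significant_{year}"]
            if pd.isna(est):
                cells += f"{'NA':>12s}{'NA':>9s}{'NA':>9s}"
            else:
                mark = "*" if sig is True else " "
                cells += f"{est:>11.3f}{mark}{lo:>9.3f}{hi:>9.3f}"
        lines.append(cells)
    lines.append("")
    lines.append("* BCa interval does not overlap zero.")
    lines.append("Squared-term estimates are doubled (gamma scale).")
    return frame, "\n".join(lines)
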