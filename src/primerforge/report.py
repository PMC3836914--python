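"""Rendering of ranked primer-pair tables as plain text, HTML or CSV.

All three formats are generated from the same row dictionaries, so
ordering and numeric values are identical across formats; coordinates are
converted here from the library's 0-based half-open convention to 1-based
inclusive for human consumption.
"""

from __future__ import annotations

import csv
import html
import io

from .candidates import PairCandidate
from .selection import RankedCandidate

FORMATS = ("text", "html", "csv")

_COLUMNS = (
    "rank",
    "forward_seq",
    "reverse_seq",
    "forward_start",
    "forward_end",
    "reverse_start",
    "reverse_end",
    "product_length",
    "forward_tm",
    "reverse_tm",
    "forward_gc",
    "reverse_gc",
    "hairpin",
    "self_dimer",
    "pair_dimer",
    "binding_sites",
    "products",
    "flags",
)


def pair_rows(ranked: list[RankedCandidate]) -> list[dict]:
    """Flatten ranked PairCandidates to report rows (1-based inclusive
    coordinates)."""
    rows = []
    for rank, r in enumerate(ranked, start=1):
        p: PairCandidate = r.item
        flags = []
        if r.suboptimal:
            flags.append("sub-optimal")
        if r.rejected:
            flags.append(f"rejected:{r.rejected_by}")
        rows.append(
            {
                "rank": rank,
                "forward_seq": p.forward.bases,
                "reverse_seq": p.reverse.bases,
                "forward_start": p.forward.start + 1,
                "forward_end": p.forward.end,
                "reverse_start": p.reverse.start + 1,
                "reverse_end": p.reverse.end,
                "product_length": p.product_length,
                "forward_tm": _fmt(p.forward.tm),
                "reverse_tm": _fmt(p.reverse.tm),
                "forward_gc": _fmt(p.forward.gc),
                "reverse_gc": _fmt(p.reverse.gc),
                "hairpin": _fmt(max(p.forward.hairpin.score, p.reverse.hairpin.score)
                                if p.forward.hairpin and p.reverse.hairpin else None),
                "self_dimer": _fmt(max(p.forward.self_dimer.score, p.reverse.self_dimer.score)
                                   if p.forward.self_dimer and p.reverse.self_dimer else None),
                "pair_dimer": _fmt(p.pair_dimer.score),
                "binding_sites": (p.forward.binding_count or 0) + (p.reverse.binding_count or 0),
                "products": p.products_count if p.products_count is not None else "",
                "flags": ";".join(flags),
            }
        )
    return rows


def _fmt(x: float | None) -> str:
    return "" if x is None else f"{x:.3f}"


def format_report(ranked: list[RankedCandidate], fmt: str = "text") -> str:
    """Render the ranked pair table in the requested format."""
    if fmt not in FORMATS:
        raise ValueError(f"unknown report format {fmt!r}; choose from {FORMATS}")
    rows = pair_rows(ranked)
    if fmt == "csv":
        return _as_csv(rows)
    if fmt == "html":
        return _as_html(rows)
    return _as_text(rows)


def _as_csv(rows: list[dict]) -> str:
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=_COLUMNS, lineterminator="\n")
    writer.writeheader()
    writer.writerows(rows)
    return buf.getvalue()


def _as_text(rows: list[dict]) -> str:
    if not rows:
        return "No primer pairs found.\n"
    widths = {c: max(len(c), max(len(str(r[c])) for r in rows)) for c in _COLUMNS}
    lines = ["  ".join(c.ljust(widths[c]) for c in _COLUMNS)]
    lines.append("  ".join("-" * widths[c] for c in _COLUMNS))
    for r in rows:
        lines.append("  ".join(str(r[c]).ljust(widths[c]) for c in _COLUMNS))
    suboptimal = any("sub-optimal" in r["flags"] for r in rows)
    if suboptimal:
        lines.append("")
        lines.append(
            "NOTE: no candidate satisfied every threshold; showing the best "
            "available sub-optimal primers."
        )
    return "\n".join(lines) + "\n"


def _as_html(rows: list[dict]) -> str:
    head = "".join(f"<th>{html.escape(c)}</th>" for c in _COLUMNS)
    body = "".join(
        "<tr>" + "".join(f"<td>{html.escape(str(r[c]))}</td>" for c in _COLUMNS) + "</tr>"
        for r in rows
    )
    empty = "" if rows else "<p>No primer pairs found.</p>"
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        "<title>Primer pair report</title></head><body>"
        f"<h1>Primer pair report</h1>{empty}"
        f"<table border='1'><thead><tr>{head}</tr></thead>"
        f"<tbody>{body}</tbody></table></body></html>\n"
    )
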