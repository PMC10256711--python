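"""Consensus donor assignment from multiple demultiplexing callers.

Combines per-droplet calls from SNP-based demultiplexers (which emit line
labels), transcription-based doublet detectors and hashtag demultiplexing
(which emit only singlet/doublet) into a retained/excluded decision per
droplet, following the retention rules used for pooled hiPSC villages:

* three-line rule: retain a droplet iff at least four callers from the
  pooled SNP + transcription set call it a singlet, the hashtag caller calls
  it a singlet, and at least three SNP callers agree on the same line.
* "at least half singlet" rule: retain iff at least ceil(K/2) of the K
  callers call singlet and a unique plurality line label exists among the
  SNP singlet calls.

Droplets missing from a caller's table count as "unassigned" (a non-singlet
vote) for that caller — the conservative choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .sim import CALLER_CLASSES, DOUBLET, SINGLET, UNASSIGNED

#: exclusion-reason clause identifiers
REASON_SINGLET_VOTES = "insufficient_singlet_votes"
REASON_HASHTAG = "hashtag_not_singlet"
REASON_LINE_AGREEMENT = "no_line_agreement"
REASON_LINE_TIE = "line_tie"
RETAINED = "retained"


def expected_doublet_count(n_droplets: int) -> float:
    """Expected number of doublets among N captured droplets: N^2 * 0.008 / 1000."""
    if n_droplets < 0:
        raise ValueError("n_droplets must be non-negative")
    return n_droplets**2 * 0.008 / 1000.0


@dataclass
class _DropletCalls:
    snp: list[str]
    transcription: list[str]
    hashtag: list[str]


def _collect(tables: list[pd.DataFrame]) -> tuple[dict[str, _DropletCalls], set[str]]:
    """Index calls by droplet, padding missing rows with 'unassigned'."""
    if not tables:
        raise ValueError("at least one assignment table is required")
    classes_seen = set()
    all_barcodes: list[str] = []
    seen = set()
    per_table: list[tuple[str, dict[str, str]]] = []
    for t in tables:
        cls = t["caller_class"].iloc[0]
        if cls not in CALLER_CLASSES:
            raise ValueError(f"unknown caller class {cls!r}")
        classes_seen.add(cls)
        per_table.append((cls, dict(zip(t["barcode"], t["call"]))))
        for b in t["barcode"]:
            if b not in seen:
                seen.add(b)
                all_barcodes.append(b)
    calls = {b: _DropletCalls([], [], []) for b in all_barcodes}
    for cls, mapping in per_table:
        for b in all_barcodes:
            getattr(calls[b], cls).append(mapping.get(b, UNASSIGNED))
    return calls, classes_seen


def _is_singlet_line(call: str) -> bool:
    """An SNP caller's call is a singlet iff it is a line label."""
    return call not in (DOUBLET, UNASSIGNED, SINGLET)


def consensus_threeline(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Apply the three-line-village retention rule to caller tables.

    Requires >=3 SNP callers and >=1 hashtag caller.  Returns one row per
    droplet with status, assigned line and the first failing clause.
    """
    calls, classes = _collect(tables)
    n_snp = sum(t["caller_class"].iloc[0] == "snp" for t in tables)
    n_hash = sum(t["caller_class"].iloc[0] == "hashtag" for t in tables)
    if n_snp < 3 or n_hash < 1:
        raise ValueError(
            f"three-line rule needs >=3 snp and >=1 hashtag callers "
            f"(got {n_snp} snp, {n_hash} hashtag)")
    rows = []
    for barcode, c in calls.items():
        snp_singlets = [x for x in c.snp if _is_singlet_line(x)]
        trans_singlets = [x for x in c.transcription if x == SINGLET]
        status, line_label, reason = "excluded", "", ""
        if len(snp_singlets) + len(trans_singlets) < 4:
            reason = REASON_SINGLET_VOTES
        elif not (c.hashtag and all(x == SINGLET for x in c.hashtag)):
            reason = REASON_HASHTAG
        elif not snp_singlets:
            reason = REASON_LINE_AGREEMENT
        else:
            counts = pd.Series(snp_singlets).value_counts()
            top = counts[counts == counts.iloc[0]]
            if counts.iloc[0] < 3:
                reason = REASON_LINE_AGREEMENT
            elif len(top) > 1:
                reason = REASON_LINE_TIE
            else:
                status, line_label, reason = RETAINED, top.index[0], RETAINED
        rows.append({"barcode": barcode, "status": status,
                     "line": line_label, "reason": reason})
    return pd.DataFrame(rows)


def consensus_at_least_half(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Retain droplets called singlet by at least half of all callers.

    With K callers, a droplet is retained iff >= ceil(K/2) callers call it a
    singlet and the SNP singlet calls have a unique plurality line label;
    ties exclude the droplet.
    """
    calls, _ = _collect(tables)
    K = len(tables)
    need = math.ceil(K / 2)
    rows = []
    for barcode, c in calls.items():
        snp_singlets = [x for x in c.snp if _is_singlet_line(x)]
        other_singlets = [x for x in c.transcription + c.hashtag if x == SINGLET]
        n_singlet = len(snp_singlets) + len(other_singlets)
        status, line_label, reason = "excluded", "", ""
        if n_singlet < need:
            reason = REASON_SINGLET_VOTES
        elif not snp_singlets:
            reason = REASON_LINE_AGREEMENT
        else:
            counts = pd.Series(snp_singlets).value_counts()
            top = counts[counts == counts.iloc[0]]
            if len(top) > 1:
                reason = REASON_LINE_TIE
            else:
                status, line_label, reason = RETAINED, top.index[0], RETAINED
        rows.append({"barcode": barcode, "status": status,
                     "line": line_label, "reason": reason})
    return pd.DataFrame(rows)


def consensus_summary(consensus: pd.DataFrame) -> dict:
    """Retained counts per line and excluded counts per failing clause."""
    retained = consensus[consensus["status"] == RETAINED]
    excluded = consensus[consensus["status"] != RETAINED]
    summary = {
        "n_droplets": len(consensus),
        "n_retained": len(retained),
        "n_excluded": len(excluded),
        "retained_per_line": retained["line"].value_counts().to_dict(),
        "excluded_per_reason": excluded["reason"].value_counts().to_dict(),
    }
    assert summary["n_retained"] + summary["n_excluded"] == len(consensus)
    return summary
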