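"""Pathogenicity-score binning, RegulomeDB rank ordering, selection filtering.

Scores are *ingested*, never computed: the module turns externally supplied
per-site numbers from seven pathogenicity predictors into categorical labels
using each tool's published or conventional cut, orders RegulomeDB
regulatory-confidence rank strings (1a strongest ... 6 weakest), and filters
selection-test records (FDIST / BayeScan / FLK) to those significant at
p or q < 0.05.

Default cuts: CADD > 20 likely deleterious; GERP > 0 conserved/likely
functional; REVEL > 0.5 likely disease causing; SIFT < 0.05 deleterious
(note the inverted direction); MetaLR > 0.5 damaging; MutationAssessor rank
>= 0.5 likely deleterious; PolyPhen-2 >= 0.85 deleterious, 0.45-0.85
intermediate, else benign.  The MetaLR, MutationAssessor and PolyPhen-2 cuts
are conventional concretizations and are configurable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

TOOLS = ("CADD", "GERP", "MutationAssessor", "REVEL", "MetaLR", "SIFT", "PolyPhen2")

DEFAULT_CUTS = {
    "CADD": 20.0,
    "GERP": 0.0,
    "MutationAssessor": 0.5,
    "REVEL": 0.5,
    "MetaLR": 0.5,
    "SIFT": 0.05,
    "PolyPhen2": (0.45, 0.85),
}

SELECTION_TESTS = ("FDIST", "BayeScan", "FLK")
SIGNIFICANCE_ALPHA = 0.05


@dataclass(frozen=True)
class ScoreRecord:
    site_id: str
    tool: str
    value: float

    def __post_init__(self):
        if self.tool not in TOOLS:
            raise ValueError(f"unknown tool {self.tool!r}")
        if not pd.notna(self.value) or self.value in (float("inf"), float("-inf")):
            raise ValueError(f"non-finite score for {self.site_id}/{self.tool}")


def bin_pathogenicity(record: ScoreRecord, cuts: dict | None = None) -> str:
    """Label one score by its tool's threshold.

    Binning is monotone per tool: raising a deleteriousness-oriented score
    (lowering, for SIFT) never moves the label toward benign.
    """
    cuts = {**DEFAULT_CUTS, **(cuts or {})}
    tool, v = record.tool, record.value
    if tool == "CADD":
        return "likely-deleterious" if v > cuts["CADD"] else "likely-benign"
    if tool == "GERP":
        return "conserved/likely-functional" if v > cuts["GERP"] else "variable"
    if tool == "REVEL":
        return "likely-disease-causing" if v > cuts["REVEL"] else "likely-benign"
    if tool == "SIFT":
        return "deleterious" if v < cuts["SIFT"] else "tolerated"
    if tool == "MetaLR":
        return "damaging" if v > cuts["MetaLR"] else "tolerated"
    if tool == "MutationAssessor":
        return "likely-deleterious" if v >= cuts["MutationAssessor"] else "benign"
    if tool == "PolyPhen2":
        lo, hi = cuts["PolyPhen2"]
        if v >= hi:
            return "deleterious"
        return "intermediate" if v >= lo else "benign"
    raise ValueError(f"unknown tool {tool!r}")


def bin_score_table(scores: pd.DataFrame, cuts: dict | None = None) -> pd.DataFrame:
    """Wide per-site table with one ``<tool>_label`` column per scored tool.

    ``scores`` columns: site_id, tool, value.
    """
    rows: dict[str, dict[str, object]] = {}
    for r in scores.itertuples(index=False):
        rec = ScoreRecord(str(r.site_id), str(r.tool), float(r.value))
        entry = rows.setdefault(rec.site_id, {"site_id": rec.site_id})
        entry[rec.tool] = rec.value
        entry[f"{rec.tool}_label"] = bin_pathogenicity(rec, cuts)
    cols = ["site_id"]
    for tool in TOOLS:
        cols += [tool, f"{tool}_label"]
    return pd.DataFrame(list(rows.values())).reindex(columns=cols)


_RANK_RE = re.compile(r"^([1-9]\d*)([a-f]?)$")


def regulome_rank_key(rank: str) -> tuple[int, str]:
    m = _RANK_RE.match(rank.strip())
    if not m:
        raise ValueError(f"malformed RegulomeDB rank {rank!r}")
    return int(m.group(1)), m.group(2)


def order_regulome_ranks(ranks: list[str]) -> list[str]:
    """Sort RegulomeDB rank strings from most to least regulatory confidence.

    Total order: numeric category major, letter subcategory minor
    (1a < 1f < 2b < 3a < 4 < 5 < 6).  The sort is stable on ties.
    """
    return sorted(ranks, key=regulome_rank_key)


def filter_selection_results(records: pd.DataFrame,
                             alpha: float = SIGNIFICANCE_ALPHA) -> pd.DataFrame:
    """Keep selection-test records with p or q value strictly below ``alpha``.

    ``records`` columns: site_id, test, statistic_kind (``p`` or ``q``),
    value.  Values must lie in [0, 1].  Idempotent; output is a subset of the
    input, sorted by site then test.
    """
    if records.empty:
        return records.copy()
    bad_test = set(records["test"]) - set(SELECTION_TESTS)
    if bad_test:
        raise ValueError(f"unknown selection tests: {sorted(bad_test)}")
    vals = records["value"].astype(float)
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("selection p/q values must be in [0, 1]")
    kept = records[vals < alpha]
    return kept.sort_values(["site_id", "test"]).reset_index(drop=True)
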