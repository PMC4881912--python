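"""Base composition, A+T content and AT/GC strand skews.

Skews follow the standard definitions AT-skew = (fA - fT)/(fA + fT) and
GC-skew = (fG - fC)/(fG + fC).  Per-class rows are computed on the
concatenated sense-strand sequences of the member genes (N-strand genes
reverse-complemented first); the whole-genome row uses the deposited
J-strand.  This is the only convention under which the J- and N-strand PCG
rows can carry opposite skew signs, as observed in insect mitogenomes.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .mito_io import AnnotatedMitogenome
from .architecture import identify_control_region

__all__ = ["BaseComposition", "base_composition", "at_skew", "gc_skew",
           "percent_at", "class_composition_report", "REPORT_CATEGORIES"]

REPORT_CATEGORIES = ("Whole", "PCG", "PCG-J", "PCG-N", "tRNA", "tRNA-J",
                     "tRNA-N", "rRNA", "rRNA-L", "rRNA-S", "Control region")


@dataclass(frozen=True)
class BaseComposition:
    fA: float
    fT: float
    fG: float
    fC: float
    n_counted: int
    n_skipped: int


def base_composition(seq: str) -> BaseComposition:
    """Tally A/T/G/C case-insensitively; other symbols are skipped."""
    if not seq:
        raise ValueError("empty sequence")
    c = Counter(seq.upper())
    n = c["A"] + c["T"] + c["G"] + c["C"]
    if n == 0:
        raise ValueError("no countable A/T/G/C bases")
    return BaseComposition(c["A"] / n, c["T"] / n, c["G"] / n, c["C"] / n,
                           n, len(seq) - n)


def at_skew(comp: BaseComposition) -> float:
    """(fA - fT)/(fA + fT); NaN when the denominator is zero."""
    denom = comp.fA + comp.fT
    return (comp.fA - comp.fT) / denom if denom > 0 else math.nan


def gc_skew(comp: BaseComposition) -> float:
    denom = comp.fG + comp.fC
    return (comp.fG - comp.fC) / denom if denom > 0 else math.nan


def percent_at(comp: BaseComposition) -> float:
    return 100.0 * (comp.fA + comp.fT)


def _row(seq: str) -> dict:
    comp = base_composition(seq)
    return {"%A+T": percent_at(comp), "AT-skew": at_skew(comp),
            "GC-skew": gc_skew(comp), "n": comp.n_counted}


def class_composition_report(genome: AnnotatedMitogenome,
                             round_output: bool = False) -> pd.DataFrame:
    """Composition/skew table with one row per feature category.

    Rows with no member features are filled with NaN.  With
    ``round_output`` the printed precision is 1 decimal for %A+T and 3 for
    skews (the usual reporting convention).
    """
    seq = genome.sequence
    groups: dict[str, list[str]] = {cat: [] for cat in REPORT_CATEGORIES}
    groups["Whole"].append(seq.residues)
    for f in genome.genes():
        sense = f.sense_sequence(seq)
        if f.feature_class == "PCG":
            groups["PCG"].append(sense)
            groups[f"PCG-{f.strand}"].append(sense)
        elif f.feature_class == "tRNA":
            groups["tRNA"].append(sense)
            groups[f"tRNA-{f.strand}"].append(sense)
        elif f.feature_class == "rRNA":
            groups["rRNA"].append(sense)
            if f.name == "rrnL":
                groups["rRNA-L"].append(sense)
            elif f.name == "rrnS":
                groups["rRNA-S"].append(sense)
    try:
        cr = identify_control_region(genome)
        groups["Control region"].append(seq.fragment(cr.start, cr.end))
    except ValueError:
        pass

    rows = {}
    for cat in REPORT_CATEGORIES:
        if groups[cat]:
            rows[cat] = _row("".join(groups[cat]))
        else:
            rows[cat] = {"%A+T": math.nan, "AT-skew": math.nan,
                         "GC-skew": math.nan, "n": 0}
    df = pd.DataFrame.from_dict(rows, orient="index").loc[list(REPORT_CATEGORIES)]
    if round_output:
        df["%A+T"] = df["%A+T"].round(1)
        df["AT-skew"] = df["AT-skew"].round(3)
        df["GC-skew"] = df["GC-skew"].round(3)
    return df
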