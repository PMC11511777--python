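"""Editing-outcome statistics: off-target and bystander averages,
normalized on/off ratio families, replicate aggregation, t-tests.

Definitions
-----------
* **Average amplicon-wide off-target editing** — the mean C•G→T•A
  conversion rate over all C/G positions of the amplicon *outside* the
  spacer (sum of per-position conversion percentages over the count of
  off-spacer C/G positions).  Positions with no coverage are excluded
  from numerator and denominator alike.
* **Average bystander editing** — the unweighted mean of per-cytosine
  rates over spacer sites other than the intended target.
* **Average unintended editing** — the unweighted mean over *all*
  non-target C/G positions, bystanders and off-spacer alike.
* **Normalized ratios** — within a cohort of editors, each editor's
  raw on/denominator ratio divided by the cohort maximum, so the best
  editor scores exactly 1.  Max-normalization is this package's
  declared choice; raw ratios are always emitted alongside.
* **Significance** — two-tailed unpaired t-tests against a reference
  condition (pooled-variance Student form by default, Welch by flag),
  with the usual star bins (* p<0.05 ... **** p<0.0001).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import MetricsError
from .genome_model import CytosineSite, SequenceRecord
from .quantifier import NucleotideCountTable

#: Default floor (percentage points) for ratio denominators when no
#: untreated-control mean is supplied.
DEFAULT_FLOOR = 0.01


@dataclass
class EditingReport:
    """The per-sample metric bundle consumed by cohort comparisons."""

    sample: str
    overall_on_target: float
    per_cytosine: dict[int, Optional[float]]
    target_index: Optional[int] = None
    avg_offtarget: Optional[float] = None
    avg_bystander: Optional[float] = None
    avg_unintended: Optional[float] = None
    ratios: dict[str, float] = field(default_factory=dict)

    @property
    def on_target_rate(self) -> float:
        """Per-cytosine rate at the target C_k if set, else overall."""
        if self.target_index is not None:
            rate = self.per_cytosine.get(self.target_index)
            if rate is None:
                raise MetricsError(f"target C_{self.target_index} has no coverage")
            return rate
        return self.overall_on_target


def _position_rates(
    table: NucleotideCountTable, rec: SequenceRecord, positions: Sequence[int]
) -> list[float]:
    """Conversion percent at reference C (%T) / G (%A) positions.

    Zero-coverage positions are dropped (missing, not zero).
    """
    rates = []
    for pos in positions:
        base = rec.seq[pos]
        conv = "T" if base == "C" else "A"
        cov = table.counts.at[pos, "coverage"]
        if cov > 0:
            rates.append(float(100.0 * table.counts.at[pos, conv] / cov))
    return rates


def avg_amplicon_offtarget(
    table: NucleotideCountTable, rec: SequenceRecord, spacer: tuple[int, int]
) -> float:
    """Mean conversion over all off-spacer C/G positions of the amplicon."""
    start, end = spacer
    if not (0 <= start <= end <= len(rec)):
        raise MetricsError(f"spacer [{start}, {end}) outside amplicon")
    positions = [
        i for i, b in enumerate(rec.seq) if b in "CG" and not (start <= i < end)
    ]
    if not positions:
        raise MetricsError("amplicon has no off-spacer C/G positions; average undefined")
    rates = _position_rates(table, rec, positions)
    if not rates:
        raise MetricsError("no covered off-spacer C/G positions; average undefined")
    return float(np.mean(rates))


def avg_bystander(
    per_cytosine: Mapping[int, Optional[float]], target_index: int
) -> float:
    """Unweighted mean editing over spacer cytosines excluding the target."""
    if target_index not in per_cytosine:
        raise MetricsError(f"target C_{target_index} not among spacer sites")
    rates = [
        r for k, r in per_cytosine.items() if k != target_index and r is not None
    ]
    if not rates:
        raise MetricsError("spacer has no bystander cytosines; average undefined")
    return float(np.mean(rates))


def avg_unintended(
    table: NucleotideCountTable,
    rec: SequenceRecord,
    spacer: tuple[int, int],
    target_pos: int,
) -> float:
    """Unweighted mean conversion over all non-target C/G positions."""
    positions = [i for i, b in enumerate(rec.seq) if b in "CG" and i != target_pos]
    if not positions:
        raise MetricsError("no non-target C/G positions; average undefined")
    rates = _position_rates(table, rec, positions)
    if not rates:
        raise MetricsError("no covered non-target C/G positions; average undefined")
    return float(np.mean(rates))


_MODE_FIELDS = {
    "off": "avg_offtarget",
    "bystander": "avg_bystander",
    "unintended": "avg_unintended",
}


def normalized_ratios(
    cohort: Sequence[EditingReport],
    mode: str = "off",
    floor: float = DEFAULT_FLOOR,
) -> list[EditingReport]:
    """On-target / denominator ratios, max-normalized within a cohort.

    ``mode`` selects the denominator family ("off", "bystander" or
    "unintended").  Denominators are floored (default 0.01 percentage
    points, or an untreated-control mean supplied by the caller) so
    zero off-target editing yields a finite ratio.  When every on-
    target value is 0 the ratios are defined as 0.
    """
    if not cohort:
        raise MetricsError("cohort is empty")
    if mode not in _MODE_FIELDS:
        raise MetricsError(f"mode must be one of {sorted(_MODE_FIELDS)}")
    fname = _MODE_FIELDS[mode]
    raws = []
    for rep in cohort:
        denom = getattr(rep, fname)
        if denom is None:
            raise MetricsError(f"report {rep.sample!r} lacks {fname}")
        raws.append(rep.on_target_rate / max(denom, floor))
    max_raw = max(raws)
    for rep, raw in zip(cohort, raws):
        rep.ratios[f"on_{mode}_raw"] = raw
        rep.ratios[f"on_{mode}_normalized"] = raw / max_raw if max_raw > 0 else 0.0
    return list(cohort)


def star_bin(p: float) -> str:
    """GraphPad-style significance stars."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def aggregate_and_test(
    groups: Mapping[str, Sequence[float]],
    reference: str,
    welch: bool = False,
) -> pd.DataFrame:
    """Replicate means ± SD plus two-tailed unpaired t-tests vs a reference.

    Student's pooled-variance form by default (Welch by flag; both
    p-values appear when ``welch`` output is requested separately).
    Conditions with a single replicate report the mean only, with a
    note.  The reference row carries no test against itself.
    """
    if reference not in groups:
        raise MetricsError(f"reference condition {reference!r} missing from groups")
    ref_vals = np.asarray(groups[reference], dtype=float)
    rows = []
    for name, values in groups.items():
        vals = np.asarray(values, dtype=float)
        row = {
            "condition": name,
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            "n": len(vals),
            "t": float("nan"),
            "p": float("nan"),
            "stars": "",
            "note": "",
        }
        if name == reference:
            row["note"] = "reference"
        elif len(vals) < 2 or len(ref_vals) < 2:
            row["note"] = "test skipped: fewer than 2 replicates"
        else:
            t, p = sps.ttest_ind(vals, ref_vals, equal_var=not welch)
            if np.allclose(vals, ref_vals) and np.isnan(t):
                t, p = 0.0, 1.0
            row.update(t=float(t), p=float(p), stars=star_bin(float(p)))
        rows.append(row)
    return pd.DataFrame(rows)
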