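"""Complex-ome statistics: substoichiometry, differential abundance and
the accumulation × synthesis group classification.

Label-free quantification (LFQ) intensities of the proteins in a
ribosome-enriched fraction carry two orthogonal signals: whether a
complex *accumulates* under a condition (differential LFQ abundance) and
whether its members are *newly synthesized* (significant 15N uptake).
Crossing the two flags classifies each complex into four response groups:

    accumulated & synthesized   → group 1
    accumulated & not degraded  → group 2  (accumulates without new 15N)
    synthesized, not accumulated→ group 3  (high turnover)
    neither                     → group 4

For ribosomal proteins, relative (sub)stoichiometry is computed by
normalizing each r-protein's abundance by the summed abundance of its own
subunit class (40S sum for SSU proteins, 60S sum for LSU proteins), which
removes the difference in assembled-subunit numbers between samples.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import bh_adjust, stars, welch_t

GO_RE = re.compile(r"^GO:\d{7}$")


@dataclass(frozen=True)
class ComplexDefinition:
    """A protein complex: display name, GO ID and member protein IDs."""

    name: str
    go_id: str
    members: tuple

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"complex {self.name!r} has no members")
        if not GO_RE.match(self.go_id):
            raise ValueError(f"invalid GO ID {self.go_id!r}")


@dataclass
class GroupCall:
    """Per-complex, per-condition classification into response groups 1–4."""

    complex_name: str
    go_id: str
    condition: str
    accumulated: bool | None
    synthesized: bool | None
    group: int | None
    n_detected: int
    accumulated_members: tuple = ()
    synthesized_members: tuple = ()
    flags: list = field(default_factory=list)


def read_complex_map(path) -> list[ComplexDefinition]:
    """TSV with columns complex, go_id, members (';'-separated protein IDs)."""
    df = pd.read_csv(path, sep="\t")
    required = {"complex", "go_id", "members"}
    if not required <= set(df.columns):
        raise ValueError(f"complex map missing column(s): {sorted(required - set(df.columns))}")
    return [
        ComplexDefinition(r.complex, r.go_id,
                          tuple(m for m in str(r.members).split(";") if m))
        for r in df.itertuples()
    ]


def substoichiometry(
    lfq: pd.DataFrame, subunit_class: Mapping[str, str]
) -> pd.DataFrame:
    """Within-subunit-class relative abundances.

    ``lfq`` is protein × sample (NaN = missing, distinct from zero);
    ``subunit_class`` maps protein IDs to a class label (e.g. ``"40S"`` /
    ``"60S"``).  value(p, s) = lfq(p, s) / Σ_{p' in class(p)} lfq(p', s),
    with missing proteins excluded from the class sum of that sample.
    Samples where a class sums to zero get NaN for that class.
    """
    if (lfq.to_numpy(dtype=float, na_value=np.nan) < 0).any():
        raise ValueError("negative LFQ intensities")
    out = pd.DataFrame(np.nan, index=lfq.index, columns=lfq.columns)
    classes: dict[str, list] = {}
    for protein in lfq.index:
        cls = subunit_class.get(protein)
        if cls is not None:
            classes.setdefault(cls, []).append(protein)
    for cls, members in classes.items():
        block = lfq.loc[members]
        sums = block.sum(axis=0, skipna=True)
        sums = sums.where(sums > 0)
        out.loc[members] = block.div(sums, axis=1)
    return out


def differential_abundance(
    lfq: pd.DataFrame,
    sample_conditions: Mapping[str, str],
    conditions: tuple[str, str],
    log2_transform: bool = True,
) -> pd.DataFrame:
    """Per-protein Welch test between two conditions with BH stars.

    Tests are run on log2 intensities (with a pseudo-intensity floor at
    each sample's 1st percentile, for variance stabilization) unless
    ``log2_transform`` is False.  Missing values are handled
    pairwise-complete — no imputation.  log2fc > 0 means higher in
    ``conditions[0]``.
    """
    cond_a, cond_b = conditions
    cols_a = [s for s in lfq.columns if sample_conditions.get(s) == cond_a]
    cols_b = [s for s in lfq.columns if sample_conditions.get(s) == cond_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicate samples per condition")
    mat = lfq.astype(float)
    if log2_transform:
        floors = mat.quantile(0.01, axis=0).replace(0, np.nan)
        floor = float(floors.min()) if np.isfinite(floors.min()) else 1.0
        mat = np.log2(mat.clip(lower=floor))
    rows = []
    for protein in mat.index:
        a = mat.loc[protein, cols_a].dropna().to_numpy()
        b = mat.loc[protein, cols_b].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            rows.append({"protein": protein, "log2fc": np.nan, "p": np.nan,
                         "skip_reason": "insufficient_values"})
            continue
        fc = float(a.mean() - b.mean()) if log2_transform else \
            float(np.log2(a.mean() / b.mean())) if a.mean() > 0 and b.mean() > 0 \
            else np.nan
        rows.append({"protein": protein, "log2fc": fc,
                     "p": welch_t(a, b, alternative="two-sided"),
                     "skip_reason": ""})
    out = pd.DataFrame(rows).set_index("protein")
    out["q"] = bh_adjust(out["p"])
    out["star"] = out["q"].apply(stars)
    return out


def classify_group(accumulated: bool | None, synthesized: bool | None) -> int | None:
    """The accumulation × synthesis truth table → response group 1–4."""
    if accumulated is None or synthesized is None:
        return None
    if accumulated and synthesized:
        return 1
    if accumulated and not synthesized:
        return 2
    if not accumulated and synthesized:
        return 3
    return 4


def _aggregate_flags(flags: Sequence[bool], rule: str) -> bool:
    if not flags:
        return False
    if rule == "any":
        return any(flags)
    if rule == "all":
        return all(flags)
    if rule == "majority":
        return sum(flags) > len(flags) / 2
    raise ValueError(f"unknown aggregation rule {rule!r}")


def classify_complex(
    cdef: ComplexDefinition,
    diff: pd.DataFrame,
    synthesized: Mapping[tuple, bool],
    condition: str,
    conditions: tuple[str, str],
    alpha: float = 0.05,
    rule: str = "majority",
) -> GroupCall:
    """Group call for one complex in one condition.

    ``diff`` is the :func:`differential_abundance` table for
    ``conditions`` (log2fc > 0 = higher in ``conditions[0]``);
    ``synthesized`` maps (protein, condition) to the protein-level
    significant-labelling flag.  A member counts as accumulated in
    ``condition`` when its differential test is significant *in that
    direction* — a complex can therefore never be accumulation-positive
    in both conditions.  Member flags are aggregated with ``rule``
    (majority by default); the positive member subsets are reported so a
    minority subset can be inspected separately.
    """
    detected = [m for m in cdef.members if m in diff.index]
    if not detected:
        return GroupCall(cdef.name, cdef.go_id, condition, None, None, None,
                         0, flags=["not_detected"])
    sign = 1.0 if condition == conditions[0] else -1.0
    acc_members = tuple(
        m for m in detected
        if (diff.loc[m, "q"] < alpha) and (sign * diff.loc[m, "log2fc"] > 0)
    )
    syn_members = tuple(
        m for m in detected if synthesized.get((m, condition), False)
    )
    acc = _aggregate_flags([m in acc_members for m in detected], rule)
    syn = _aggregate_flags([m in syn_members for m in detected], rule)
    return GroupCall(
        cdef.name, cdef.go_id, condition, acc, syn,
        classify_group(acc, syn), len(detected),
        accumulated_members=acc_members, synthesized_members=syn_members,
    )


def classify_all(
    complexes: Sequence[ComplexDefinition],
    diff: pd.DataFrame,
    synthesized: Mapping[tuple, bool],
    conditions: tuple[str, str],
    alpha: float = 0.05,
    rule: str = "majority",
) -> pd.DataFrame:
    """Group calls for every complex in both conditions (wide table)."""
    rows = []
    for cdef in complexes:
        row = {"complex": cdef.name, "go_id": cdef.go_id}
        for cond in conditions:
            call = classify_complex(cdef, diff, synthesized, cond, conditions,
                                    alpha=alpha, rule=rule)
            row[f"group_{cond}"] = call.group
            row[f"accumulated_members_{cond}"] = ";".join(call.accumulated_members)
            row[f"synthesized_members_{cond}"] = ";".join(call.synthesized_members)
            row["n_detected"] = call.n_detected
        rows.append(row)
    return pd.DataFrame(rows)


def subunit_ratio(
    lfq: pd.DataFrame, subunit_class: Mapping[str, str],
    large: str = "60S", small: str = "40S",
) -> tuple[pd.Series, float]:
    """Per-sample LSU:SSU summed-abundance ratio and the r² of the sums.

    A constant ratio with high r² across samples indicates that the
    numbers of assembled large and small subunits are co-regulated.
    """
    lsu = [p for p in lfq.index if subunit_class.get(p) == large]
    ssu = [p for p in lfq.index if subunit_class.get(p) == small]
    if not lsu or not ssu:
        raise ValueError("both subunit classes must be present")
    lsum = lfq.loc[lsu].sum(axis=0, skipna=True)
    ssum = lfq.loc[ssu].sum(axis=0, skipna=True)
    ratio = lsum / ssum.where(ssum > 0)
    if len(lsum) >= 3 and ssum.std() > 0 and lsum.std() > 0:
        r = np.corrcoef(ssum, lsum)[0, 1]
        r2 = float(r * r)
    else:
        r2 = float("nan")
    return ratio, r2
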