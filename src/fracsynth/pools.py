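"""Soluble amino-acid pool 15N enrichment from GC–MS fragment tables.

Free amino acids are the proxy for aminoacyl-tRNA charging: the tracer
fraction of each soluble pool bounds how much 15N a newly made peptide
can carry.  Each amino acid is measured through several mass fragments
(electron-impact or APCI in-source fragments of the derivatized analyte),
each with its own elemental formula and isotopologue envelope.  This
module applies the NIA correction per fragment, quality-controls the
fragments against each other and against the non-labelled controls, picks
the most precise clean fragment per amino acid, and compares the
resulting pool enrichments across treatments (ANOVA + Tukey HSD).

Input is a tidy TSV with one row per (fragment, sample):
``amino_acid, fragment_id, formula, sample_id, condition, replicate,
tech_rep, labelled, M0..Mk`` — trailing M columns may be empty when a
fragment uses a shorter envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import nia
from .chem import ElementalFormula
from .stats import AnovaTukeyResult, anova_tukey

#: amino acids reported by full analyte name are mapped to one-letter codes;
#: pyroglutamate is an extraction/derivatization product of glutamine.
ANALYTE_ALIASES = {
    "pyroglutamate": "Q",
    "pyroglutamic_acid": "Q",
    "pyroglutamic acid": "Q",
    "glycine": "G", "alanine": "A", "serine": "S", "proline": "P",
    "valine": "V", "threonine": "T", "cysteine": "C", "leucine": "L",
    "isoleucine": "I", "asparagine": "N", "aspartate": "D", "glutamine": "Q",
    "lysine": "K", "glutamate": "E", "methionine": "M", "histidine": "H",
    "phenylalanine": "F", "arginine": "R", "tyrosine": "Y", "tryptophan": "W",
}

#: |mean control enrichment| below this is "null enrichment in the control"
NULL_CONTROL_THRESHOLD = 0.002

#: summed-isotopologue Pearson correlation below this flags a fragment pair
CONSISTENCY_THRESHOLD = 0.8


def canonical_aa(name: str) -> str:
    name = str(name).strip()
    if len(name) == 1 and name.isalpha():
        return name.upper()
    return ANALYTE_ALIASES.get(name.lower().replace("-", "_"), name)


@dataclass
class AAEnrichmentTable:
    """Per-condition, per-amino-acid tracer enrichment of the soluble pools.

    ``table`` has columns condition, amino_acid, e_a, sd, fragment_id,
    flags.  Amino acids absent from the table (below the detection limit,
    or failing every fragment QC gate) are queried as e_a = 0.
    """

    table: pd.DataFrame

    def enrichments(self, condition: str) -> dict[str, float]:
        sub = self.table[self.table["condition"] == condition]
        return {
            row.amino_acid: float(row.e_a)
            for row in sub.itertuples()
            if np.isfinite(row.e_a) and row.e_a > 0
        }

    def get(self, condition: str, amino_acid: str) -> float:
        return self.enrichments(condition).get(canonical_aa(amino_acid), 0.0)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AAEnrichmentTable":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_dict(cls, per_condition: Mapping[str, Mapping[str, float]]
                  ) -> "AAEnrichmentTable":
        rows = [
            {"condition": cond, "amino_acid": canonical_aa(aa), "e_a": e,
             "sd": np.nan, "fragment_id": "direct", "flags": ""}
            for cond, table in per_condition.items()
            for aa, e in table.items()
        ]
        return cls(pd.DataFrame(rows))


def _envelope_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith("M") and c[1:].isdigit()]
    return sorted(cols, key=lambda c: int(c[1:]))


def read_fragments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"amino_acid", "fragment_id", "formula", "sample_id",
                "condition", "replicate", "labelled"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fragment table is missing column(s): {sorted(missing)}")
    if not _envelope_columns(df):
        raise ValueError("fragment table has no M0.. isotopologue columns")
    df = df.copy()
    df["amino_acid"] = df["amino_acid"].map(canonical_aa)
    df["labelled"] = df["labelled"].astype(bool)
    if "tech_rep" not in df.columns:
        df["tech_rep"] = 1
    return df


def fragment_pair_consistency(
    fragments: pd.DataFrame, threshold: float = CONSISTENCY_THRESHOLD
) -> tuple[pd.DataFrame, list[tuple]]:
    """Pearson correlation of per-sample summed-isotopologue abundances.

    Because 15N feeding redistributes intensity between isotopologues of
    the same fragment, fragments of one analyte are compared on the sum of
    all measured isotopologues rather than on monoisotopic abundance.
    Returns the fragment × fragment correlation matrix and the list of
    pairs below ``threshold``.
    """
    ids = sorted(fragments["fragment_id"].unique())
    if len(ids) < 2:
        raise ValueError("fragment_pair_consistency needs >= 2 fragments")
    env_cols = _envelope_columns(fragments)
    sums = fragments.assign(total=fragments[env_cols].sum(axis=1, skipna=True))
    wide = sums.pivot_table(index="sample_id", columns="fragment_id",
                            values="total")
    if wide.shape[0] < 3:
        raise ValueError("fragment_pair_consistency needs >= 3 samples")
    corr = wide[ids].corr(method="pearson")
    flagged = [
        (a, b)
        for i, a in enumerate(ids)
        for b in ids[i + 1:]
        if corr.loc[a, b] < threshold
    ]
    return corr, flagged


def fragment_enrichment(
    fragment: pd.DataFrame, purity: float = 0.99
) -> pd.DataFrame:
    """Per-sample NIA-corrected enrichment for one fragment.

    All N atoms of a GC–MS fragment descend from the parent amino acid, so
    the labelable-atom count is the fragment's full N count.  Returns the
    sample metadata plus ``enrichment`` and ``residual`` columns.
    """
    formulas = fragment["formula"].unique()
    if len(formulas) != 1:
        raise ValueError(f"fragment rows disagree on formula: {formulas}")
    formula = ElementalFormula.parse(formulas[0])
    n_label = formula["N"]
    if n_label < 1:
        raise ValueError("fragment without nitrogen cannot report 15N enrichment")
    env_cols = _envelope_columns(fragment)
    out = []
    A = None
    for row in fragment.itertuples():
        env = np.array([getattr(row, c) for c in env_cols], dtype=float)
        env = env[~np.isnan(env)]
        if A is None or A.n_peaks != len(env):
            A = nia.correction_matrix(formula, n_label, len(env), purity=purity)
        corr = nia.correct_envelope(env, A)
        out.append({
            "sample_id": row.sample_id,
            "condition": row.condition,
            "replicate": row.replicate,
            "tech_rep": row.tech_rep,
            "labelled": row.labelled,
            "enrichment": corr.enrichment,
            "residual": corr.residual,
        })
    return pd.DataFrame(out)


def pooled_fragment_enrichment(
    fragment: pd.DataFrame, purity: float = 0.99
) -> dict:
    """Enrichment of the envelope summed over sample groups.

    Returns ``{(condition, labelled): enrichment}`` plus the all-control
    pool under ``("*", False)``.  Summing envelopes before the NNLS
    deconvolution shrinks the non-negativity bias of the per-sample
    estimates, which matters most for the control samples whose true
    enrichment is zero (the per-sample estimator can only err upward
    there).
    """
    formula = ElementalFormula.parse(fragment["formula"].iloc[0])
    n_label = formula["N"]
    env_cols = _envelope_columns(fragment)
    out: dict = {}
    groups = list(fragment.groupby(["condition", "labelled"]))
    ctrl = fragment[~fragment["labelled"]]
    if len(ctrl):
        groups.append((("*", False), ctrl))
    A = None
    for key, sub in groups:
        env = sub[env_cols].sum(axis=0, skipna=True).to_numpy(dtype=float)
        env = env[: int(sub[env_cols].notna().any(axis=0).sum())]
        if env.sum() <= 0:
            continue
        if A is None or A.n_peaks != len(env):
            A = nia.correction_matrix(formula, n_label, len(env), purity=purity)
        out[key] = nia.correct_envelope(env, A).enrichment
    return out


@dataclass
class FragmentSelection:
    """Outcome of the per-amino-acid fragment QC for one condition."""

    amino_acid: str
    condition: str
    fragment_id: str | None
    enrichment: float  # mean across biological replicates (post-subtraction)
    sd: float
    rsd: float
    per_replicate: pd.Series  # biological-replicate means
    baseline_subtracted: bool = False
    flags: list = field(default_factory=list)


def _bio_means(enr: pd.DataFrame) -> pd.Series:
    """Pool technical replicates within biological replicates first."""
    return enr.groupby("replicate")["enrichment"].mean()


def select_fragments(
    enrichments: pd.DataFrame,
    condition: str,
    null_threshold: float = NULL_CONTROL_THRESHOLD,
    min_fragments: int = 3,
    pooled: Mapping[tuple, float] | None = None,
) -> FragmentSelection:
    """Choose the reporting fragment for one amino acid in one condition.

    ``enrichments`` holds per-sample corrected enrichments for every
    candidate fragment of one amino acid (columns as produced by
    :func:`fragment_enrichment` plus ``fragment_id``).  The gates are:

    1. fragments whose mean enrichment in the non-labelled control exceeds
       the null threshold are discarded — unless *every* fragment is
       non-null, in which case the analyte is treated as technically
       biased: the mean control "enrichment" is subtracted from the
       labelled samples and the fragments with minimal post-subtraction
       control variance are retained;
    2. among survivors, the fragment with the lowest relative standard
       deviation across replicates (technical pooled within biological
       first) is chosen.

    Negative post-subtraction enrichments are clipped to zero and flagged.
    If nothing survives, the amino acid is reported undetected (e_a = 0).

    ``pooled`` optionally supplies summed-envelope enrichments keyed by
    ``(fragment_id, condition, labelled)`` (with ``condition = "*"`` for
    the all-control pool); when given, control baselines and the reported
    mean use these lower-bias estimates while replicate spread (RSD)
    still comes from the per-sample values.
    """
    aa = enrichments["amino_acid"].iloc[0] if "amino_acid" in enrichments else "?"
    frag_ids = sorted(enrichments["fragment_id"].unique())
    flags: list[str] = []
    if len(frag_ids) < min_fragments:
        flags.append(f"fewer_than_{min_fragments}_fragments")

    control = enrichments[~enrichments["labelled"]]
    labelled = enrichments[enrichments["labelled"]
                           & (enrichments["condition"] == condition)]
    if labelled.empty:
        return FragmentSelection(aa, condition, None, 0.0, np.nan, np.nan,
                                 pd.Series(dtype=float),
                                 flags=flags + ["undetected"])

    ctrl_mean = control.groupby("fragment_id")["enrichment"].mean()
    if pooled is not None:
        ctrl_mean = pd.Series({
            f: pooled.get((f, "*", False), ctrl_mean.get(f, 0.0))
            for f in frag_ids
        })
    clean = [f for f in frag_ids
             if abs(ctrl_mean.get(f, 0.0)) < null_threshold]

    subtract = False
    if not clean:
        # all fragments carry residual control "enrichment": technical bias
        subtract = True
        flags.append("baseline_subtracted")
        ctrl_var = control.groupby("fragment_id")["enrichment"].var()
        min_var = ctrl_var.min()
        clean = [f for f in frag_ids
                 if np.isclose(ctrl_var.get(f, np.inf), min_var, rtol=0.5)]

    best: FragmentSelection | None = None
    for f in clean:
        sub = labelled[labelled["fragment_id"] == f]
        if sub.empty:
            continue
        vals = _bio_means(sub)
        if subtract:
            vals = vals - ctrl_mean.get(f, 0.0)
        mean = float(vals.mean())
        if pooled is not None and (f, condition, True) in pooled:
            mean = float(pooled[(f, condition, True)])
            if subtract:
                mean -= float(ctrl_mean.get(f, 0.0))
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        rsd = sd / abs(mean) if mean and np.isfinite(sd) else np.inf
        cand = FragmentSelection(aa, condition, f, mean, sd, rsd, vals,
                                 baseline_subtracted=subtract, flags=list(flags))
        if best is None or cand.rsd < best.rsd:
            best = cand
    if best is None:
        return FragmentSelection(aa, condition, None, 0.0, np.nan, np.nan,
                                 pd.Series(dtype=float),
                                 flags=flags + ["undetected"])
    if best.enrichment < 0:
        sd = best.sd if np.isfinite(best.sd) else 0.0
        if best.enrichment < -2 * sd:
            best.flags.append("negative_beyond_2sd")
        best.flags.append("clipped_negative")
        best.per_replicate = best.per_replicate.clip(lower=0.0)
        best.enrichment = 0.0
    return best


def build_enrichment_table(
    fragments: pd.DataFrame,
    purity: float = 0.99,
    null_threshold: float = NULL_CONTROL_THRESHOLD,
) -> tuple[AAEnrichmentTable, pd.DataFrame]:
    """Run the full pool pipeline on a tidy fragment table.

    Returns the per-condition enrichment table and the per-sample
    fragment-level enrichments (for the cross-treatment statistics).
    """
    all_enr = []
    pooled: dict[tuple, float] = {}
    for (aa, frag), group in fragments.groupby(["amino_acid", "fragment_id"]):
        enr = fragment_enrichment(group, purity=purity)
        enr.insert(0, "amino_acid", aa)
        enr.insert(1, "fragment_id", frag)
        all_enr.append(enr)
        for (cond, lab), value in pooled_fragment_enrichment(
                group, purity=purity).items():
            pooled[(frag, cond, lab)] = value
    enr_df = pd.concat(all_enr, ignore_index=True)

    conditions = sorted(enr_df["condition"].unique())
    rows = []
    for aa, group in enr_df.groupby("amino_acid"):
        for cond in conditions:
            sel = select_fragments(group, cond, null_threshold=null_threshold,
                                   pooled=pooled)
            e_a = sel.enrichment
            flags = list(sel.flags)
            if 0 < e_a < null_threshold:
                # indistinguishable from an unlabelled pool: treat as 0
                e_a = 0.0
                flags.append("below_null_threshold")
            rows.append({
                "condition": cond,
                "amino_acid": aa,
                "e_a": e_a,
                "sd": sel.sd,
                "fragment_id": sel.fragment_id or "",
                "flags": ";".join(flags),
            })
    return AAEnrichmentTable(pd.DataFrame(rows)), enr_df


def compare_pool_enrichments(
    enr_df: pd.DataFrame, alpha: float = 0.05
) -> dict[str, AnovaTukeyResult]:
    """ANOVA + Tukey HSD of pool enrichments across treatment groups.

    Groups are condition × labelled combinations (the non-labelled
    controls are genuine groups in the comparison, as on the enrichment
    boxplots).  Values are biological-replicate means of the per-sample
    corrected enrichments, pooled over fragments.
    """
    out = {}
    for aa, group in enr_df.groupby("amino_acid"):
        groups = {}
        for (cond, lab), sub in group.groupby(["condition", "labelled"]):
            key = f"{cond}/{'L' if lab else 'NL'}"
            vals = sub.groupby("replicate")["enrichment"].mean()
            if len(vals) >= 2:
                groups[key] = vals.to_numpy()
        if len(groups) >= 2:
            out[aa] = anova_tukey(groups, alpha=alpha)
    return out
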