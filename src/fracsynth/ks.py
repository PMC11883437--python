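"""Fractional protein synthesis rates (Ks) from corrected peptide enrichments.

The chain per peptide and condition is:

* LPF — the labelled-peptide fraction, i.e. the NIA-corrected mean
  enrichment over the peptide's labelable N atoms, averaged across
  labelled biological replicates;
* significance filtering — a one-sided Welch t-test of the labelled
  replicates against the non-labelled controls (or against zero when no
  controls exist), BH-adjusted across all peptides, combined with
  replicate-count, fit-residual and envelope-completeness gates;
* E_max — the maximum attainable LPF: the mean pool enrichment a fully
  newly synthesized molecule would show over the labelable-atom set,
  E_max = Σ nN(a)·e_a / Σ nN(a) over residues with e_a > 0, using the
  pools of the peptide's own condition;
* corrected LPF = LPF / E_max — the fraction of the peptide's molecules
  synthesized during the labelling window (fraction-new);
* Ks = corrected LPF × RGR × 100, in % h⁻¹, using the condition-average
  dry-weight RGR as the physiological normalizer.

Protein-level values are medians over passing peptides; peptides shared
between protein groups are discarded so paralogue-specific synthesis is
never mixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import ResidueTable, RESIDUES
from .stats import bh_adjust, stars, welch_t

DEFAULT_ALPHA = 0.05
DEFAULT_RESIDUAL_MAX = 0.1
DEFAULT_COMPLETENESS_MIN = 0.8
CORRECTED_LPF_CAP = 1.5  # corrected LPF above 1 is flagged, above this rejected


def max_lpf(
    sequence: str,
    pool_enrichments: Mapping[str, float],
    residues: ResidueTable | None = None,
) -> float:
    """E_max: enrichment of a hypothetical fully newly synthesized peptide.

    Only residues with non-zero pool enrichment enter numerator and
    denominator — the same labelable-atom convention the NIA correction
    uses for its enrichment denominator, so LPF/E_max is internally
    consistent.  Returns NaN when the peptide has no labelable atoms.
    """
    residues = residues or RESIDUES
    num = 0.0
    den = 0
    for ch in sequence:
        e_a = float(pool_enrichments.get(ch, 0.0))
        if e_a > 0:
            n_n = residues.nitrogen(ch)
            num += n_n * e_a
            den += n_n
    if den == 0:
        return float("nan")
    return num / den


def corrected_lpf(lpf: float, e_max: float) -> tuple[float, list]:
    """LPF / E_max with physical-range flags (not silently truncated)."""
    if not np.isfinite(e_max) or e_max <= 0:
        raise ValueError("E_max must be positive")
    value = lpf / e_max
    flags = []
    if value > CORRECTED_LPF_CAP:
        flags.append("corrected_lpf_above_cap")
    elif value > 1:
        flags.append("pool_underestimate")
    return value, flags


def ks_rate(corrected: float, rgr_avg: float) -> float:
    """Ks = corrected LPF × RGR × 100, in % h⁻¹."""
    return corrected * rgr_avg * 100.0


def lpf_filter(
    enrichments: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    residual_max: float = DEFAULT_RESIDUAL_MAX,
    completeness_min: float = DEFAULT_COMPLETENESS_MIN,
) -> pd.DataFrame:
    """Significance and quality filtering of per-peptide enrichments.

    ``enrichments`` is tidy per-sample data with columns ``analyte_id,
    condition, replicate, labelled, enrichment, residual`` and optionally
    ``completeness``.  Per (analyte, condition): a one-sided Welch t-test
    of labelled replicates above max(0, control mean); BH adjustment is
    applied across all tested peptides; passing requires q < alpha, at
    least two labelled replicates, mean NNLS residual <= residual_max and
    envelope completeness >= completeness_min.

    Returns one row per (analyte_id, condition) with p, q, pass_filter and
    fail_reason columns — the funnel counts behind the filter are
    recoverable by tabulating fail_reason.
    """
    rows = []
    for (analyte, cond), group in enrichments.groupby(["analyte_id", "condition"]):
        lab = group.loc[group["labelled"], "enrichment"].dropna()
        unlab = group.loc[~group["labelled"], "enrichment"].dropna()
        lab_rows = group[group["labelled"]]
        completeness = (
            float(lab_rows["completeness"].mean())
            if "completeness" in group and len(lab_rows) else 1.0
        )
        residual = float(group.loc[group["labelled"], "residual"].mean())
        reasons = []
        if len(lab) < 2:
            reasons.append("insufficient_replicates")
            p = float("nan")
        else:
            if len(unlab) >= 2 and unlab.mean() > 0:
                p = welch_t(lab, unlab, alternative="greater")
            else:
                p = welch_t(lab, popmean=0.0, alternative="greater")
        if residual > residual_max:
            reasons.append("high_residual")
        if completeness < completeness_min:
            reasons.append("incomplete_envelope")
        rows.append({
            "analyte_id": analyte,
            "condition": cond,
            "lpf": float(lab.mean()) if len(lab) else float("nan"),
            "lpf_sd": float(lab.std(ddof=1)) if len(lab) > 1 else float("nan"),
            "control_mean": float(unlab.mean()) if len(unlab) else float("nan"),
            "n_labelled": int(len(lab)),
            "n_control": int(len(unlab)),
            "residual": residual,
            "completeness": completeness,
            "p": p,
            "fail_reason": ";".join(reasons),
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = bh_adjust(out["p"])
    not_sig = ~(out["q"] < alpha)
    out.loc[not_sig & out["p"].notna(), "fail_reason"] = (
        out.loc[not_sig & out["p"].notna(), "fail_reason"]
        .apply(lambda r: ";".join(filter(None, [r, "not_significant"])))
    )
    out["pass_filter"] = (out["fail_reason"] == "")
    return out


def filter_funnel(filtered: pd.DataFrame) -> pd.DataFrame:
    """Gate-by-gate counts of peptides surviving the filter chain."""
    total = len(filtered)
    gates = ["insufficient_replicates", "high_residual",
             "incomplete_envelope", "not_significant"]
    rows = [{"gate": "tested", "n_remaining": total}]
    mask = pd.Series(True, index=filtered.index)
    for gate in gates:
        mask &= ~filtered["fail_reason"].str.contains(gate, na=False)
        rows.append({"gate": f"after_{gate}", "n_remaining": int(mask.sum())})
    return pd.DataFrame(rows)


def peptide_synthesis(
    filtered: pd.DataFrame,
    sequences: Mapping[str, str],
    pools,
    rgr_avg: Mapping[str, float],
    residues: ResidueTable | None = None,
) -> pd.DataFrame:
    """Per-peptide synthesis table: LPF, E_max, corrected LPF, Ks.

    ``filtered`` is the output of :func:`lpf_filter`; ``sequences`` maps
    analyte IDs to peptide sequences; ``pools`` is an AAEnrichmentTable
    (E_max uses the pools of each peptide's own condition); ``rgr_avg``
    maps conditions to average dry-weight RGRs.
    """
    rows = []
    for rec in filtered.itertuples():
        seq = sequences.get(rec.analyte_id)
        if seq is None:
            seq = rec.analyte_id.split("/")[0]
        e_map = pools.enrichments(rec.condition)
        e_max = max_lpf(seq, e_map, residues)
        flags = []
        if not np.isfinite(e_max):
            value = float("nan")
            rate = float("nan")
            flags.append("no_labelable_atoms")
        else:
            value, flags = corrected_lpf(rec.lpf, e_max)
            rate = ks_rate(value, rgr_avg[rec.condition])
        rows.append({
            "analyte_id": rec.analyte_id,
            "sequence": seq,
            "condition": rec.condition,
            "lpf": rec.lpf,
            "e_max": e_max,
            "corrected_lpf": value,
            "ks": rate,
            "q": rec.q,
            "pass_filter": bool(rec.pass_filter) and np.isfinite(e_max),
            "n_labelled": rec.n_labelled,
            "flags": ";".join(flags),
        })
    return pd.DataFrame(rows)


def aggregate_protein(
    peptides: pd.DataFrame,
    protein_map: Mapping[str, Sequence[str]],
    min_passing: int = 1,
    discard_shared: bool = True,
) -> pd.DataFrame:
    """Protein-level synthesis: median corrected LPF and Ks over passing peptides.

    ``protein_map`` maps analyte IDs to the protein groups they match.
    Peptides mapping to more than one protein are discarded by default
    (razor assignment off): synthesis rates must not mix paralogues.
    Proteins whose peptides all fail the filter are still reported, with
    the not-synthesized flag and no rate.
    """
    rows = []
    by_protein: dict[str, list] = {}
    for rec in peptides.itertuples():
        prots = list(protein_map.get(rec.analyte_id, ()))
        if not prots:
            continue
        if discard_shared and len(prots) > 1:
            continue
        for p in prots:
            by_protein.setdefault(p, []).append(rec)
    for protein, recs in sorted(by_protein.items()):
        for cond in sorted({r.condition for r in recs}):
            sub = [r for r in recs if r.condition == cond]
            passing = [r for r in sub if r.pass_filter]
            if len(passing) >= min_passing:
                clpf = float(np.median([r.corrected_lpf for r in passing]))
                rate = float(np.median([r.ks for r in passing]))
                disp = float(np.median(np.abs(
                    np.array([r.ks for r in passing]) - rate)))
                rows.append({
                    "protein": protein, "condition": cond,
                    "n_peptides": len(passing), "n_peptides_total": len(sub),
                    "median_corrected_lpf": clpf, "median_ks": rate,
                    "ks_mad": disp, "synthesized": True, "flags": "",
                })
            else:
                rows.append({
                    "protein": protein, "condition": cond,
                    "n_peptides": 0, "n_peptides_total": len(sub),
                    "median_corrected_lpf": float("nan"),
                    "median_ks": float("nan"), "ks_mad": float("nan"),
                    "synthesized": False, "flags": "not_synthesized",
                })
    return pd.DataFrame(rows)


def replicate_corrected_lpf(
    enrichments: pd.DataFrame,
    sequences: Mapping[str, str],
    pools,
    protein_map: Mapping[str, Sequence[str]],
    residues: ResidueTable | None = None,
    discard_shared: bool = True,
) -> pd.DataFrame:
    """Per-replicate protein-level corrected LPFs (for condition contrasts).

    Each labelled replicate contributes, per protein and condition, the
    median over the protein's unique peptides of enrichment / E_max.
    """
    rows = []
    lab = enrichments[enrichments["labelled"]]
    for (cond, repl), group in lab.groupby(["condition", "replicate"]):
        e_map = pools.enrichments(cond)
        per_protein: dict[str, list] = {}
        for rec in group.itertuples():
            prots = list(protein_map.get(rec.analyte_id, ()))
            if not prots or (discard_shared and len(prots) > 1):
                continue
            seq = sequences.get(rec.analyte_id, rec.analyte_id.split("/")[0])
            e_max = max_lpf(seq, e_map, residues)
            if not np.isfinite(e_max) or e_max <= 0:
                continue
            per_protein.setdefault(prots[0], []).append(rec.enrichment / e_max)
        for protein, vals in per_protein.items():
            rows.append({
                "protein": protein, "condition": cond, "replicate": repl,
                "corrected_lpf": float(np.median(vals)), "n_peptides": len(vals),
            })
    return pd.DataFrame(rows)


def compare_ks(
    replicate_lpf: pd.DataFrame,
    conditions: tuple[str, str],
) -> pd.DataFrame:
    """Differential synthesis between two conditions.

    Two-sided Welch t-test per protein on the per-replicate corrected
    LPFs, BH adjustment across proteins, stars at q < 0.1 / 0.05 / 0.01.
    Proteins missing one of the two conditions (or with < 2 replicates in
    either) are skipped with a reason.
    """
    cond_a, cond_b = conditions
    rows = []
    for protein, group in replicate_lpf.groupby("protein"):
        a = group.loc[group["condition"] == cond_a, "corrected_lpf"].to_numpy()
        b = group.loc[group["condition"] == cond_b, "corrected_lpf"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            rows.append({
                "protein": protein, "mean_a": np.nan, "mean_b": np.nan,
                "log2fc": np.nan, "p": np.nan,
                "skip_reason": "missing_condition_or_replicates",
            })
            continue
        with np.errstate(divide="ignore"):
            l2fc = (np.log2(a.mean()) - np.log2(b.mean())
                    if a.mean() > 0 and b.mean() > 0 else np.nan)
        rows.append({
            "protein": protein,
            "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "log2fc": float(l2fc) if np.isfinite(l2fc) else np.nan,
            "p": welch_t(a, b, alternative="two-sided"),
            "skip_reason": "",
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = bh_adjust(out["p"])
    out["star"] = out["q"].apply(lambda q: stars(q) if np.isfinite(q) else "")
    return out
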