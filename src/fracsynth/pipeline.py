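"""End-to-end orchestration: evidence + MS1 + pools + growth → Ks tables.

This is the glue the command-line ``all`` subcommand and the tests use;
each step is a thin call into the corresponding module so the stages stay
individually testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import ks as ks_mod
from . import mzio, nia
from .chem import count_labelable_atoms, formula_of_peptide
from .pools import AAEnrichmentTable


def read_ms1_sources(path: str | Path) -> dict[str, mzio.PeakTable]:
    """Load MS1 peak data keyed by raw file.

    A single mzML file maps every raw file to the same spectra; the TSV
    fallback may carry a ``raw_file`` column to hold several acquisitions
    in one table.
    """
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        table = mzio.PeakTable.from_mzml(path)
        return {"*": table}
    df = pd.read_csv(path, sep="\t")
    if "raw_file" not in df.columns:
        return {"*": mzio.PeakTable.from_tsv(path)}
    out = {}
    for raw, group in df.groupby("raw_file"):
        scans = [
            (rt, g["mz"].to_numpy(), g["intensity"].to_numpy())
            for (_, rt), g in group.groupby(["scan", "rt_min"], sort=True)
        ]
        out[str(raw)] = mzio.PeakTable(scans)
    return out


@dataclass
class PipelineResult:
    """Every table the workflow produces, peptide level up to protein level."""

    enrichments: pd.DataFrame  # per analyte × sample corrected enrichment
    filtered: pd.DataFrame  # lpf_filter output
    peptides: pd.DataFrame  # peptide synthesis table (LPF, E_max, Ks)
    proteins: pd.DataFrame  # protein-level medians
    replicate_lpf: pd.DataFrame  # per-replicate protein corrected LPFs
    differential: pd.DataFrame | None = None  # compare_ks output
    funnel: pd.DataFrame | None = None
    sequences: dict = field(default_factory=dict)
    protein_map: dict = field(default_factory=dict)

    def synthesized_flags(self) -> dict:
        """(protein, condition) → significant-labelling flag, for group calls."""
        return {
            (r.protein, r.condition): bool(r.synthesized)
            for r in self.proteins.itertuples()
        }


def correct_envelopes(
    records: list,
    spectra: Mapping[str, mzio.PeakTable],
    pools: AAEnrichmentTable,
    purity: float = 0.99,
    ppm_tol: float = mzio.DEFAULT_PPM_TOL,
    rt_halfwidth_min: float = mzio.DEFAULT_RT_HALFWIDTH_MIN,
    natural_tail_cutoff: float = 0.999,
) -> pd.DataFrame:
    """Extract, sum (per sequence × charge × sample) and NIA-correct envelopes.

    Returns ``(enrichments, pooled)``: the tidy per-sample enrichment
    table consumed by the filters, plus the per-(analyte, condition) LPF
    computed from the envelope summed over labelled replicates.  The
    pooled estimate is the preferred point estimate — deconvolving the
    lower-noise summed envelope shrinks the non-negativity bias of the
    NNLS fit — while the per-sample values feed the replicate-level
    significance test.  The peak count and the labelable-atom count are
    per peptide *and* per condition, because the labelable set depends on
    which pools are enriched in that condition.
    """
    groups = mzio.group_evidence(records)
    matrices: dict[tuple, nia.CorrectionMatrix] = {}
    pooled: dict[tuple, np.ndarray] = {}
    rows = []
    for (seq, charge, raw), recs in groups.items():
        rec = recs[0]
        cond = rec.condition
        e_map = pools.enrichments(cond) if cond else {}
        formula = formula_of_peptide(seq)
        lab = count_labelable_atoms(seq, e_map)
        n_peaks = mzio.optimal_peak_count(
            formula, lab.n_labelable, natural_tail_cutoff=natural_tail_cutoff
        )
        source = spectra.get(raw, spectra.get("*"))
        if source is None:
            continue
        total = np.zeros(n_peaks)
        found_any = False
        for r in recs:  # multiple evidence rows per sample: envelopes summed
            env = mzio.extract_envelope(
                source, r, n_peaks, ppm_tol=ppm_tol,
                rt_halfwidth_min=rt_halfwidth_min,
            )
            total += env.intensities
            found_any = found_any or env.found
        if lab.n_labelable < 1 or not found_any or total.sum() <= 0:
            continue
        key = (seq, cond, n_peaks)
        if key not in matrices:
            matrices[key] = nia.correction_matrix(
                formula, lab.n_labelable, n_peaks, purity=purity
            )
        corr = nia.correct_envelope(total, matrices[key])
        # a peak counts as expected (hence "missing" when absent) only if
        # the fitted forward model predicts appreciable mass there
        predicted = matrices[key].matrix @ corr.fractions
        expected = predicted >= 0.01 * predicted.max()
        completeness = float((total[expected] > 0).mean())
        if rec.labelled:
            # replicate-summed envelope: the low-noise input for the
            # pooled LPF point estimate (NNLS bias grows with noise)
            pkey = (rec.analyte_id, cond)
            if pkey not in pooled:
                pooled[pkey] = [matrices[key], np.zeros(n_peaks)]
            pooled[pkey][1] = pooled[pkey][1] + total
        rows.append({
            "analyte_id": rec.analyte_id,
            "sequence": seq,
            "charge": charge,
            "raw_file": raw,
            "condition": cond,
            "replicate": rec.replicate,
            "labelled": rec.labelled,
            "proteins": ";".join(rec.proteins),
            "enrichment": corr.enrichment,
            "labelled_fraction": corr.labelled_fraction,
            "residual": corr.residual,
            "n_peaks": n_peaks,
            "completeness": completeness,
        })
    pooled_rows = [
        {"analyte_id": analyte, "condition": cond,
         "lpf_pooled": nia.correct_envelope(env, A).enrichment}
        for (analyte, cond), (A, env) in pooled.items()
        if env.sum() > 0
    ]
    return pd.DataFrame(rows), pd.DataFrame(pooled_rows)


def run_pipeline(
    records: list,
    spectra: Mapping[str, mzio.PeakTable],
    pools: AAEnrichmentTable,
    rgr_avg: Mapping[str, float],
    purity: float = 0.99,
    alpha: float = ks_mod.DEFAULT_ALPHA,
    compare_conditions: tuple | None = None,
    **extract_kw,
) -> PipelineResult:
    """The full peptide-to-protein synthesis-rate workflow."""
    enr, pooled = correct_envelopes(records, spectra, pools, purity=purity,
                                    **extract_kw)
    if enr.empty:
        raise ValueError("no envelopes could be extracted and corrected")
    sequences = {r.analyte_id: r.sequence for r in enr.itertuples()}
    protein_map = {
        r.analyte_id: tuple(p for p in r.proteins.split(";") if p)
        for r in enr.itertuples()
    }
    filtered = ks_mod.lpf_filter(enr, alpha=alpha)
    if not pooled.empty:
        filtered = filtered.merge(pooled, on=["analyte_id", "condition"],
                                  how="left")
        filtered["lpf_replicate_mean"] = filtered["lpf"]
        filtered["lpf"] = filtered["lpf_pooled"].fillna(filtered["lpf"])
    peptides = ks_mod.peptide_synthesis(filtered, sequences, pools, rgr_avg)
    proteins = ks_mod.aggregate_protein(peptides, protein_map)
    replicate_lpf = ks_mod.replicate_corrected_lpf(
        enr, sequences, pools, protein_map
    )
    differential = None
    if compare_conditions is not None:
        differential = ks_mod.compare_ks(replicate_lpf, compare_conditions)
    return PipelineResult(
        enrichments=enr,
        filtered=filtered,
        peptides=peptides,
        proteins=proteins,
        replicate_lpf=replicate_lpf,
        differential=differential,
        funnel=ks_mod.filter_funnel(filtered),
        sequences=sequences,
        protein_map=protein_map,
    )
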