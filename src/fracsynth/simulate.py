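"""Forward generative model for every input the pipeline consumes.

The simulator emulates the measurement process end to end with known
ground truth, so each stage — envelope extraction, NIA correction, pool
enrichment, growth normalization, differential statistics — can be tested
without any external data:

* peptide isotopologue envelopes are mixtures of old (natural-abundance)
  and new (pool-enriched) molecules: with fraction-new f, each labelable N
  atom of a new molecule is heavy with probability
  e_a·purity + (1 − e_a)·p_nat, convolved with the natural isotopes of
  all remaining atoms;
* GC–MS amino-acid fragments follow the same model with the fragment's own
  N count, with configurable contaminated fragments and all-biased analytes
  to exercise every fragment-QC branch;
* growth curves are built so that the fraction-of-final-weight RGR
  averaged over the labelling window equals the configured truth exactly
  in the noiseless limit;
* LFQ matrices carry configurable per-protein fold changes and a 60S:40S
  subunit structure.

The default configuration mirrors the study design: two conditions (cold
4 °C vs optimal-temperature control), three biological replicates each for
labelled and non-labelled seedlings, technical triplicates for the GC–MS
pools, a 99%-pure 15N serine/glycine tracer entering the pools at ~15%
(cold) vs ~4% (control) for Ser/Gly with weaker spread into other amino
acids, 5% multiplicative intensity noise, dry-weight RGRs of 0.017 (cold)
and 0.008 h⁻¹ (control) over a 120 h labelling window, and a Lys-C
digest (cleavage C-terminal to lysine only).
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .chem import (
    ElementalFormula,
    ISOTOPES,
    RESIDUES,
    WATER,
    count_labelable_atoms,
    formula_of_peptide,
    natural_distribution,
    peptide_mz,
)
from .mzio import DEFAULT_ISOTOPE_SPACING, optimal_peak_count

DEFAULT_POOLS = {
    "cold": {"S": 0.15, "G": 0.15, "Q": 0.05, "E": 0.05, "N": 0.05,
             "P": 0.04, "V": 0.03, "D": 0.04, "F": 0.03, "I": 0.03},
    "control": {"S": 0.04, "G": 0.04, "Q": 0.03, "E": 0.03, "N": 0.025},
}

DEFAULT_RGR = {"cold": 0.017, "control": 0.008}

#: amino-acid alphabet used for random peptides (no K inside a peptide —
#: Lys-C leaves K only at the C-terminus; H/R excluded to mimic the basic
#: residues being rare targets in the digest and undetected in the pools)
PEPTIDE_ALPHABET = "GASPVTLINDQEF"


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic dataset."""

    seed: int
    conditions: tuple = ("cold", "control")
    n_bio: int = 3
    n_tech_pools: int = 3
    n_proteins: int = 50
    peptides_per_protein: int = 10
    peptide_length: tuple = (6, 16)  # residues before the C-terminal K
    charge: int = 2
    fraction_new: dict = field(default_factory=dict)  # protein -> {cond: f}
    f_grid: tuple = (0.05, 0.2, 0.5)
    pool_enrichments: dict = field(default_factory=lambda: {
        c: dict(t) for c, t in DEFAULT_POOLS.items()})
    purity: float = 0.99
    cv: float = 0.05  # multiplicative intensity noise
    additive_floor: float = 0.0  # SD of additive (detector) noise, counts
    rgr: dict = field(default_factory=lambda: dict(DEFAULT_RGR))
    t_f: float = 120.0
    time_points: tuple = (24.0, 48.0, 72.0, 96.0, 120.0)
    w_final: dict = field(default_factory=lambda: {"cold": 2.0, "control": 2.5})
    growth_cv: float = 0.0
    lfq_fold_change: dict = field(default_factory=dict)  # protein -> cold/control FC
    lfq_cv: float = 0.1
    fragments_per_aa: int = 3
    contaminated_fragments: dict = field(default_factory=dict)  # (aa, idx) -> bias
    all_biased_aas: dict = field(default_factory=dict)  # aa -> bias
    natural_tail_cutoff: float = 0.999
    rt_start_min: float = 5.0
    rt_spacing_min: float = 1.05
    scan_offsets_min: tuple = (-0.4, -0.2, 0.0, 0.2, 0.4)
    scan_weights: tuple = (0.3, 0.7, 1.0, 0.7, 0.3)

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def lysc_digest(protein: str, min_len: int = 2) -> list[str]:
    """Lys-C cleavage: split C-terminal to every lysine."""
    peptides, start = [], 0
    for i, ch in enumerate(protein):
        if ch == "K":
            peptides.append(protein[start:i + 1])
            start = i + 1
    if start < len(protein):
        peptides.append(protein[start:])
    return [p for p in peptides if len(p) >= min_len]


def make_proteome(config: SimConfig) -> dict[str, str]:
    """Seeded random proteome of Lys-C-friendly proteins."""
    rng = config.rng(1)
    lo, hi = config.peptide_length
    proteome = {}
    seen = set()
    for i in range(config.n_proteins):
        parts = []
        for _ in range(config.peptides_per_protein):
            while True:
                length = int(rng.integers(lo, hi + 1))
                pep = "".join(rng.choice(list(PEPTIDE_ALPHABET), size=length)) + "K"
                if pep not in seen:  # keep peptides protein-unique
                    seen.add(pep)
                    break
            parts.append(pep)
        proteome[f"P{i:04d}"] = "".join(parts)
    return proteome


def assign_fractions(config: SimConfig, proteome: Mapping[str, str]) -> dict:
    """Fill in per-protein, per-condition true fraction-new values."""
    rng = config.rng(2)
    out = {}
    for protein in proteome:
        if protein in config.fraction_new:
            out[protein] = dict(config.fraction_new[protein])
        else:
            out[protein] = {c: float(rng.choice(config.f_grid))
                            for c in config.conditions}
    return out


def _bernoulli_convolve(base: np.ndarray, probs) -> np.ndarray:
    out = base.copy()
    n = len(out)
    for p in probs:
        out = np.convolve(out, [1.0 - p, p])[:n]
    return out


def mixture_envelope(
    sequence: str,
    f: float,
    e_map: Mapping[str, float],
    n_peaks: int,
    purity: float = 0.99,
) -> np.ndarray:
    """Noiseless theoretical envelope of an old/new molecule mixture.

    Built directly from per-atom Bernoulli convolutions — independent of
    the NIA correction-matrix construction, so round trips through the
    correction are genuine two-route checks.
    """
    formula = formula_of_peptide(sequence)
    nat = natural_distribution(formula, ISOTOPES, n_peaks)
    if f == 0:
        return nat
    lab = count_labelable_atoms(sequence, e_map)
    reduced = formula.remove(ISOTOPES.label_element, lab.n_labelable)
    base = natural_distribution(reduced, ISOTOPES, n_peaks)
    p_nat = ISOTOPES.natural_heavy_abundance("N")
    probs = []
    for _res, _pos, n_n, e_a, labelable in lab.breakdown:
        if labelable:
            probs.extend([e_a * purity + (1.0 - e_a) * p_nat] * n_n)
    new = _bernoulli_convolve(base, probs)
    return (1.0 - f) * nat + f * new


def _sample_key(condition: str, replicate: int, labelled: bool) -> str:
    return f"{condition}_{'L' if labelled else 'NL'}_rep{replicate}"


def simulate_envelopes(
    config: SimConfig,
    proteome: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Evidence table + MS1 peak table + truth for the peptide-level data.

    Returns ``(evidence, ms1, truth)`` where ``evidence`` is a
    MaxQuant-dialect TSV frame (one row per peptide × sample), ``ms1``
    holds centroided peaks (columns raw_file, scan, rt_min, mz, intensity)
    and ``truth`` records the realized per-protein fraction-new values.
    """
    proteome = proteome or make_proteome(config)
    fractions = assign_fractions(config, proteome)
    rng = config.rng(3)

    peptide_rows = []
    for protein, seq in proteome.items():
        for pep in lysc_digest(seq):
            peptide_rows.append((pep, protein))
    # peptide -> proteins (shared peptides keep every parent)
    pep_proteins: dict[str, list] = {}
    for pep, protein in peptide_rows:
        pep_proteins.setdefault(pep, []).append(protein)
    peptides = sorted(pep_proteins)

    evidence = []
    ms1 = []
    for pi, pep in enumerate(peptides):
        mz0 = peptide_mz(pep, config.charge)
        rt_apex = config.rt_start_min + pi * config.rt_spacing_min
        abundance = float(rng.lognormal(np.log(1e6), 0.3))
        for cond in config.conditions:
            e_map = config.pool_enrichments.get(cond, {})
            lab_count = count_labelable_atoms(pep, e_map)
            n_peaks = optimal_peak_count(
                formula_of_peptide(pep), lab_count.n_labelable,
                natural_tail_cutoff=config.natural_tail_cutoff,
            )
            f_values = [fractions[p][cond] for p in pep_proteins[pep]]
            f = float(np.mean(f_values))
            for labelled in (True, False):
                env = mixture_envelope(
                    pep, f if labelled else 0.0, e_map, n_peaks, config.purity
                )
                for rep in range(1, config.n_bio + 1):
                    raw = _sample_key(cond, rep, labelled)
                    noisy = env * abundance
                    if config.cv > 0:
                        noisy = noisy * np.clip(
                            1.0 + config.cv * rng.standard_normal(n_peaks), 0, None
                        )
                    if config.additive_floor > 0:
                        noisy = np.clip(
                            noisy + config.additive_floor
                            * rng.standard_normal(n_peaks), 0, None
                        )
                    evidence.append({
                        "Sequence": pep,
                        "Charge": config.charge,
                        "m/z": mz0,
                        "Retention time": rt_apex,
                        "Raw file": raw,
                        "Proteins": ";".join(pep_proteins[pep]),
                        "Intensity": float(noisy.sum()),
                        "Condition": cond,
                        "Replicate": rep,
                        "Labelled": labelled,
                    })
                    for si, (off, w) in enumerate(
                        zip(config.scan_offsets_min, config.scan_weights)
                    ):
                        rt = rt_apex + off
                        for i in range(n_peaks):
                            if noisy[i] <= 0:
                                continue
                            ms1.append({
                                "raw_file": raw,
                                "scan": pi * len(config.scan_offsets_min) + si,
                                "rt_min": rt,
                                "mz": mz0 + i * DEFAULT_ISOTOPE_SPACING / config.charge,
                                "intensity": noisy[i] * w,
                            })
    truth = {
        "fraction_new": fractions,
        "pool_enrichments": {c: dict(t) for c, t in config.pool_enrichments.items()},
        "rgr": dict(config.rgr),
        "expected_ks": {
            p: {c: fractions[p][c] * config.rgr[c] * 100.0
                for c in config.conditions}
            for p in fractions
        },
        "purity": config.purity,
    }
    return pd.DataFrame(evidence), pd.DataFrame(ms1), truth


_TMS_UNIT = ElementalFormula({"C": 3, "H": 9, "Si": 1})


def fragment_formula(aa: str, index: int) -> ElementalFormula:
    """Synthetic derivatized-fragment formula: free amino acid + index TMS-like
    units (a stand-in for real electron-impact fragment annotations)."""
    return RESIDUES.formula(aa) + WATER + _TMS_UNIT * (index + 1)


def simulate_pools(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Tidy GC–MS fragment table exercising every fragment-QC branch.

    Fragments listed in ``config.contaminated_fragments`` carry an
    artifact heavy-isotope bias in *all* samples (so their control
    enrichment is non-null and they must be excluded); amino acids in
    ``config.all_biased_aas`` have the bias on every fragment (so the
    baseline-subtraction branch must engage).
    """
    rng = config.rng(4)
    p_nat = ISOTOPES.natural_heavy_abundance("N")
    aas = sorted({aa for t in config.pool_enrichments.values() for aa in t})
    rows = []
    for aa in aas:
        for idx in range(config.fragments_per_aa):
            formula = fragment_formula(aa, idx)
            n_n = formula["N"]
            n_peaks = optimal_peak_count(
                formula, n_n, natural_tail_cutoff=config.natural_tail_cutoff
            )
            bias = config.all_biased_aas.get(
                aa, config.contaminated_fragments.get((aa, idx), 0.0)
            )
            reduced = formula.remove("N", n_n)
            base = natural_distribution(reduced, ISOTOPES, n_peaks)
            for cond in config.conditions:
                e_a = config.pool_enrichments.get(cond, {}).get(aa, 0.0)
                for labelled in (True, False):
                    # the artifact bias behaves like extra tracer-derived
                    # signal present in labelled AND control samples
                    frac = (e_a if labelled else 0.0) + bias
                    p = min(frac * config.purity + (1 - frac) * p_nat, 1.0)
                    env = _bernoulli_convolve(base, [p] * n_n)
                    for rep in range(1, config.n_bio + 1):
                        for tech in range(1, config.n_tech_pools + 1):
                            scale = float(rng.lognormal(np.log(1e5), 0.2))
                            noisy = env * scale
                            if config.cv > 0:
                                noisy = noisy * np.clip(
                                    1.0 + config.cv * rng.standard_normal(n_peaks),
                                    0, None,
                                )
                            row = {
                                "amino_acid": aa,
                                "fragment_id": f"{aa}_frag{idx}",
                                "formula": formula.to_string(),
                                "sample_id": f"{_sample_key(cond, rep, labelled)}_t{tech}",
                                "condition": cond,
                                "replicate": rep,
                                "tech_rep": tech,
                                "labelled": labelled,
                            }
                            for i in range(n_peaks):
                                row[f"M{i}"] = noisy[i]
                            rows.append(row)
    truth = {c: dict(t) for c, t in config.pool_enrichments.items()}
    return pd.DataFrame(rows), truth


def simulate_growth(config: SimConfig, variable: str = "DW",
                    n_plants: int = 6) -> pd.DataFrame:
    """Weight time series whose window-averaged RGR matches the configured truth.

    The per-time RGR profile r_t is a peaked template (transient cold
    acceleration) scaled so that (a) its unweighted mean over the daily
    time points equals the configured average RGR and (b) r at t_f equals
    1/t_f, which the definition W(t_f) = W_f forces.  Weights are then
    W_t = W_f · r_t · t plus optional multiplicative noise.
    """
    rng = config.rng(5)
    times = np.asarray(config.time_points, dtype=float)
    t_f = config.t_f
    rows = []
    for cond in config.conditions:
        target = config.rgr[cond]
        if target is None:  # zero growth: constant weight, RGR_t = 1/t
            r = 1.0 / times
            w = np.full_like(times, config.w_final[cond])
            for t, w_t in zip(times, w):
                for plant in range(1, n_plants + 1):
                    rows.append({"condition": cond, "replicate": plant,
                                 "time_h": t, "variable": variable,
                                 "value": w_t})
            continue
        template = np.where(times < t_f, np.exp(-((times - 72.0) / 30.0) ** 2), 0.0)
        mean_template = template.mean()
        s = (target - 1.0 / t_f) / mean_template
        r = 1.0 / t_f + s * template
        w = config.w_final[cond] * r * times
        for t, w_t in zip(times, w):
            for plant in range(1, n_plants + 1):
                value = w_t
                if config.growth_cv > 0:
                    value *= max(0.0, 1.0 + config.growth_cv * rng.standard_normal())
                rows.append({
                    "condition": cond, "replicate": plant, "time_h": t,
                    "variable": variable, "value": value,
                })
    return pd.DataFrame(rows)


def simulate_lfq(
    config: SimConfig, proteome: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Protein × sample LFQ matrix with configured cold/control fold changes.

    Returns ``(lfq, sample_meta)``; fold changes default to 1 (no
    accumulation) for proteins absent from ``config.lfq_fold_change``.
    """
    proteome = proteome or make_proteome(config)
    rng = config.rng(6)
    samples = []
    meta = []
    for cond in config.conditions:
        for rep in range(1, config.n_bio + 1):
            name = f"{cond}_rep{rep}"
            samples.append(name)
            meta.append({"sample": name, "condition": cond, "replicate": rep})
    data = {}
    for protein in proteome:
        base = float(rng.lognormal(np.log(1e8), 0.5))
        fc = float(config.lfq_fold_change.get(protein, 1.0))
        row = []
        for m in meta:
            mean = base * (fc if m["condition"] == config.conditions[0] else 1.0)
            row.append(mean * max(0.0, 1.0 + config.lfq_cv * rng.standard_normal()))
        data[protein] = row
    lfq = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    return lfq, pd.DataFrame(meta)


def simulate_dataset(config: SimConfig, outdir: str | Path) -> dict:
    """Write every pipeline input (TSV) plus truth.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteome = make_proteome(config)
    evidence, ms1, truth = simulate_envelopes(config, proteome)
    frags, pool_truth = simulate_pools(config)
    weights = simulate_growth(config)
    lfq, meta = simulate_lfq(config, proteome)
    evidence.to_csv(outdir / "evidence.tsv", sep="\t", index=False)
    ms1.to_csv(outdir / "ms1.tsv", sep="\t", index=False)
    frags.to_csv(outdir / "pool_fragments.tsv", sep="\t", index=False)
    weights.to_csv(outdir / "weights.tsv", sep="\t", index=False)
    lfq.rename_axis("protein").to_csv(outdir / "lfq.tsv", sep="\t")
    meta.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    with open(outdir / "fasta.fasta", "w") as fh:
        for pid, seq in proteome.items():
            fh.write(f">{pid}\n{seq}\n")
    truth["pool_truth"] = pool_truth
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth


def recovery_report(
    truth: dict,
    peptide_table: pd.DataFrame,
    tolerance_bias: float = 0.01,
    tolerance_rmse: float = 0.03,
) -> pd.DataFrame:
    """Bias/RMSE of recovered fraction-new against the simulated truth.

    ``peptide_table`` is the per-peptide synthesis table (needs columns
    sequence or analyte_id, condition, corrected_lpf); peptides are
    matched to protein truth through the fraction_new map by the protein
    each condition's table rows carry, so the table must also have a
    ``protein`` column, or the truth is joined per analyte via
    ``truth['peptide_truth']`` when present.
    """
    frames = []
    f_truth = truth["fraction_new"]
    if "protein" not in peptide_table.columns:
        raise ValueError("peptide table needs a 'protein' column for the report")
    for cond, group in peptide_table.groupby("condition"):
        true_f = group["protein"].map(
            lambda p: f_truth.get(p, {}).get(cond, np.nan))
        err = group["corrected_lpf"] - true_f
        err = err.dropna()
        frames.append({
            "condition": cond,
            "n": int(err.shape[0]),
            "bias": float(err.mean()),
            "rmse": float(np.sqrt((err ** 2).mean())),
            "pass": bool(abs(err.mean()) < tolerance_bias
                         and np.sqrt((err ** 2).mean()) < tolerance_rmse),
        })
    return pd.DataFrame(frames)
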