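"""Peptide identification tables, MS1 peak data and envelope extraction.

The identification side consumes a MaxQuant-evidence-style TSV (the search
engine already localized each peptide in m/z and retention time); the MS1
side re-reads the centroided survey scans and recovers the full
isotopologue envelope M0 … M+k around each identification.  The number of
peaks k+1 is optimized per peptide from its molecular formula and the
soluble-pool enrichments, so that highly labelable peptides get a wide
window and short ones are not diluted with empty peaks.

MS1 data are accepted either as mzML (read with pyteomics) or as a plain
peak-table TSV with columns ``scan, rt_min, mz, intensity`` — the two are
interchangeable everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import (
    ElementalFormula,
    IsotopePolicy,
    ISOTOPES,
    ResidueTable,
    count_labelable_atoms,
    formula_of_peptide,
    natural_distribution,
    peptide_mz,
)

logger = logging.getLogger("fracsynth")

#: spacing between isotopologue peaks, Th·z.  The 13C spacing (MaxQuant
#: convention); the 15N spacing (0.99703) difference is absorbed by the
#: ppm tolerance at survey-scan resolution for i <= 6.
DEFAULT_ISOTOPE_SPACING = 1.00335

DEFAULT_PPM_TOL = 10.0
DEFAULT_RT_HALFWIDTH_MIN = 0.5

MANDATORY_EVIDENCE_COLUMNS = (
    "Sequence",
    "Charge",
    "m/z",
    "Retention time",
    "Raw file",
    "Proteins",
    "Intensity",
)


@dataclass
class PeptideRecord:
    """One evidence row: a peptide located in one raw file."""

    sequence: str
    charge: int
    mz: float
    rt_apex_min: float
    raw_file: str
    proteins: tuple
    intensity: float = float("nan")
    condition: str | None = None
    replicate: str | None = None
    labelled: bool | None = None
    flags: list = field(default_factory=list)

    @property
    def analyte_id(self) -> str:
        return f"{self.sequence}/{self.charge}"


@dataclass
class IsotopologueEnvelope:
    """Ordered M0..Mk intensities for one analyte in one sample."""

    analyte_id: str
    intensities: np.ndarray
    charge: int
    mz_centers: np.ndarray
    raw_file: str
    found: bool = True

    @property
    def n_peaks(self) -> int:
        return len(self.intensities)


def read_evidence(path: str | Path) -> list[PeptideRecord]:
    """Read a MaxQuant-evidence-dialect TSV into peptide records.

    Extra columns are ignored; the optional ``Condition``, ``Replicate``
    and ``Labelled`` columns (written by the simulator, or added by the
    user from their sample sheet) are carried through when present.  Rows
    with missing mandatory fields are dropped and counted in the log.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANDATORY_EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"evidence table is missing mandatory column(s): {missing}")
    records: list[PeptideRecord] = []
    dropped = 0
    for row in df.itertuples(index=False):
        data = dict(zip(df.columns, row))
        try:
            seq = str(data["Sequence"]).strip()
            charge = int(float(data["Charge"]))
            mz = float(data["m/z"])
            rt = float(data["Retention time"])
            raw = str(data["Raw file"]).strip()
            if not seq or seq.lower() == "nan" or not raw or raw.lower() == "nan":
                raise ValueError
        except (TypeError, ValueError):
            dropped += 1
            continue
        proteins = tuple(
            p for p in str(data.get("Proteins", "")).split(";") if p and p != "nan"
        )
        try:
            intensity = float(data.get("Intensity"))
        except (TypeError, ValueError):
            intensity = float("nan")
        labelled = data.get("Labelled")
        if labelled is not None and str(labelled).lower() not in ("nan", ""):
            labelled = str(labelled).strip().lower() in ("1", "true", "yes", "l")
        else:
            labelled = None
        rec = PeptideRecord(
            sequence=seq,
            charge=charge,
            mz=mz,
            rt_apex_min=rt,
            raw_file=raw,
            proteins=proteins,
            intensity=intensity,
            condition=_opt_str(data.get("Condition")),
            replicate=_opt_str(data.get("Replicate")),
            labelled=labelled,
        )
        _flag_record(rec)
        records.append(rec)
    if dropped:
        logger.warning("read_evidence: dropped %d row(s) with missing mandatory fields",
                       dropped)
    return records


def _opt_str(v) -> str | None:
    if v is None:
        return None
    s = str(v).strip()
    return s if s and s.lower() != "nan" else None


def _flag_record(rec: PeptideRecord) -> None:
    if not 1 <= rec.charge <= 8:
        rec.flags.append("charge_out_of_range")
    try:
        theo = peptide_mz(rec.sequence, rec.charge)
    except Exception:
        rec.flags.append("unknown_residue")
        return
    if abs(rec.mz - theo) / theo * 1e6 > 25:
        rec.flags.append("mz_anchor_off")


def optimal_peak_count(
    formula: ElementalFormula,
    n_labelable: int,
    policy: IsotopePolicy | None = None,
    natural_tail_cutoff: float = 0.999,
    max_natural_peaks: int = 64,
) -> int:
    """Per-peptide envelope width: n_labelable + n_nat + 1 peaks.

    ``n_nat`` is the smallest j such that the cumulative natural
    distribution of the non-label elements (formula with the label element
    removed) reaches ``natural_tail_cutoff`` — wide enough that the
    natural 13C tail of a fully labelled molecule still falls inside the
    window.
    """
    if not 0.99 < natural_tail_cutoff < 1:
        raise ValueError("natural_tail_cutoff must be in (0.99, 1)")
    policy = policy or ISOTOPES
    nolabel = ElementalFormula(
        {el: n for el, n in formula.counts.items() if el != policy.label_element}
    )
    dist = natural_distribution(nolabel, policy, max_natural_peaks)
    cum = np.cumsum(dist)
    idx = np.searchsorted(cum, natural_tail_cutoff)
    n_nat = int(min(idx, max_natural_peaks - 1))
    return n_labelable + n_nat + 1


def peak_count_for_peptide(
    sequence: str,
    pool_enrichments: Mapping[str, float],
    residues: ResidueTable | None = None,
    policy: IsotopePolicy | None = None,
    natural_tail_cutoff: float = 0.999,
) -> tuple[int, int]:
    """Convenience wrapper returning ``(n_peaks, n_labelable)`` for a sequence."""
    formula = formula_of_peptide(sequence, residues)
    lab = count_labelable_atoms(sequence, pool_enrichments, residues)
    n_peaks = optimal_peak_count(
        formula, lab.n_labelable, policy, natural_tail_cutoff
    )
    return n_peaks, lab.n_labelable


class PeakTable:
    """Centroided MS1 scans held as (rt, mz[], intensity[]) triples."""

    def __init__(self, scans: Sequence[tuple]):
        self.scans = [
            (float(rt), np.asarray(mz, dtype=float), np.asarray(inten, dtype=float))
            for rt, mz, inten in sorted(scans, key=lambda s: s[0])
        ]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PeakTable":
        """Read the plain peak-table fallback: scan, rt_min, mz, intensity."""
        df = pd.read_csv(path, sep="\t")
        required = {"scan", "rt_min", "mz", "intensity"}
        if not required <= set(df.columns):
            raise ValueError(
                f"MS1 TSV is missing column(s): {sorted(required - set(df.columns))}"
            )
        scans = []
        for (_, rt), g in df.groupby(["scan", "rt_min"], sort=True):
            scans.append((rt, g["mz"].to_numpy(), g["intensity"].to_numpy()))
        return cls(scans)

    @classmethod
    def from_mzml(cls, path: str | Path) -> "PeakTable":
        """Read centroided MS1 scans from an mzML file."""
        from pyteomics import mzml as _mzml

        scans = []
        with _mzml.MzML(str(path)) as reader:
            for spec in reader:
                if spec.get("ms level") != 1:
                    continue
                rt = _scan_rt_minutes(spec)
                scans.append((rt, spec["m/z array"], spec["intensity array"]))
        return cls(scans)

    @classmethod
    def open(cls, path: str | Path) -> "PeakTable":
        path = Path(path)
        if path.suffix.lower() == ".mzml":
            return cls.from_mzml(path)
        return cls.from_tsv(path)

    def scans_in_window(self, rt_lo: float, rt_hi: float) -> list[tuple]:
        return [s for s in self.scans if rt_lo <= s[0] <= rt_hi]


def _scan_rt_minutes(spec) -> float:
    scan = spec["scanList"]["scan"][0]
    rt = scan["scan start time"]
    unit = getattr(rt, "unit_info", "minute")
    rt = float(rt)
    return rt / 60.0 if unit == "second" else rt


def extract_envelope(
    spectra: PeakTable,
    peptide: PeptideRecord,
    n_peaks: int,
    ppm_tol: float = DEFAULT_PPM_TOL,
    rt_halfwidth_min: float = DEFAULT_RT_HALFWIDTH_MIN,
    spacing: float = DEFAULT_ISOTOPE_SPACING,
) -> IsotopologueEnvelope:
    """Sum the most intense centroid near each isotopologue m/z per scan.

    For i = 0 … n_peaks−1 the target is ``mz0 + i·spacing/z``; within each
    MS1 scan inside ``apex ± rt_halfwidth`` the most intense centroid
    within ±ppm_tol of the target is taken, and intensities are summed
    across scans.  A missing peak contributes zero; if no MS1 scan covers
    the retention-time window the envelope is all zeros and flagged not
    found.
    """
    targets = peptide.mz + np.arange(n_peaks) * spacing / peptide.charge
    window = spectra.scans_in_window(
        peptide.rt_apex_min - rt_halfwidth_min, peptide.rt_apex_min + rt_halfwidth_min
    )
    intensities = np.zeros(n_peaks)
    if not window:
        return IsotopologueEnvelope(
            peptide.analyte_id, intensities, peptide.charge, targets,
            peptide.raw_file, found=False,
        )
    for _rt, mz, inten in window:
        if len(mz) == 0:
            continue
        tol = targets * ppm_tol * 1e-6
        lo = np.searchsorted(mz, targets - tol, side="left")
        hi = np.searchsorted(mz, targets + tol, side="right")
        for i in range(n_peaks):
            if hi[i] > lo[i]:
                intensities[i] += inten[lo[i]:hi[i]].max()
    found = intensities.sum() > 0
    return IsotopologueEnvelope(
        peptide.analyte_id, intensities, peptide.charge, targets,
        peptide.raw_file, found=found,
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein ID → sequence from a FASTA file (first token of the header)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def group_evidence(
    records: Iterable[PeptideRecord],
) -> dict[tuple, list[PeptideRecord]]:
    """Group evidence rows by (sequence, charge, raw file) for envelope summing."""
    groups: dict[tuple, list[PeptideRecord]] = {}
    for rec in records:
        groups.setdefault((rec.sequence, rec.charge, rec.raw_file), []).append(rec)
    return groups
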