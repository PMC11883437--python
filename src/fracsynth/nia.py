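"""Natural-isotopic-abundance (NIA) correction of isotopologue envelopes.

A measured envelope m (intensities at M0 … M+k) is modelled as A·x where
column j of the correction matrix A is the envelope a molecule with
exactly j deliberately labelled atoms would produce, and x_j is the
fraction of molecules carrying j labelled atoms.  Solving for x by
non-negative least squares removes the natural 13C/15N/2H/17O/18O/33S/34S
signal and any tracer impurity, leaving the deliberate labelling.

The mean isotopic enrichment E = Σ_j j·x_j / n_label is the fraction of
labelable atoms that are tracer-derived — the per-analyte enrichment
statistic used both for soluble amino-acid pools and for peptides (where
it is the labelled-peptide fraction, LPF).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from scipy.stats import binom

from .chem import ElementalFormula, IsotopePolicy, ISOTOPES, natural_distribution


class EmptyEnvelopeError(ValueError):
    """Raised when an all-zero envelope is submitted for correction."""


@dataclass(frozen=True)
class CorrectionMatrix:
    """Forward model A[i, j] = P(j-labelled molecule observed at peak i)."""

    matrix: np.ndarray  # shape (n_peaks, n_label + 1)
    n_label: int
    formula: ElementalFormula
    purity: float

    @property
    def n_peaks(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class CorrectedEnvelope:
    """NNLS-deconvolved isotopologue fractions and enrichment summaries."""

    fractions: np.ndarray  # x_j, j = 0..n_label, normalized to sum 1
    residual: float  # NNLS residual norm on the sum-normalized envelope
    enrichment: float  # mean enrichment E = sum j x_j / n_label
    labelled_fraction: float  # 1 - x_0, the alternative LPF statistic
    n_label: int


def correction_matrix(
    formula: ElementalFormula,
    n_label: int,
    n_peaks: int,
    policy: IsotopePolicy | None = None,
    purity: float = 0.99,
) -> CorrectionMatrix:
    """Build the NIA correction matrix for ``n_label`` labelable atoms.

    Column j is the natural distribution of the formula with j label-element
    atoms removed, shifted by the j deliberately labelled atoms.  Tracer
    impurity is applied as binomial thinning: each deliberately labelled
    atom is heavy with probability ``purity``, light otherwise.  The
    remaining (non-labelled) label-element atoms stay at natural abundance
    inside the reduced formula.
    """
    policy = policy or ISOTOPES
    label = policy.label_element
    if n_label > formula[label]:
        raise ValueError(
            f"n_label={n_label} exceeds {label} count {formula[label]} of formula"
        )
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    shift = policy.label_shift
    A = np.zeros((n_peaks, n_label + 1))
    for j in range(n_label + 1):
        base = natural_distribution(formula.remove(label, j), policy, n_peaks)
        # j labelled atoms contribute m heavy ones ~ Binomial(j, purity)
        col = np.zeros(n_peaks)
        for m in range(j + 1):
            w = binom.pmf(m, j, purity) if j else (1.0 if m == 0 else 0.0)
            if w == 0.0 or m * shift >= n_peaks:
                continue
            col[m * shift:] += w * base[: n_peaks - m * shift]
        A[:, j] = col
    return CorrectionMatrix(A, n_label, formula, purity)


def mean_enrichment(fractions: np.ndarray, n_label: int) -> float:
    """E = Σ_j j·x_j / n_label — the mean labelled fraction per labelable atom."""
    if n_label < 1:
        raise ValueError("enrichment undefined for n_label = 0")
    x = np.asarray(fractions, dtype=float)
    return float(np.arange(len(x)) @ x / n_label)


def correct_envelope(
    intensities: np.ndarray, A: CorrectionMatrix
) -> CorrectedEnvelope:
    """Deconvolve an envelope into labelled-atom-count fractions.

    Solves ``x = argmin ||A·x − m||₂  s.t.  x ≥ 0`` on the sum-normalized
    envelope, then renormalizes x to sum 1.  NNLS rather than matrix
    inversion because truncated envelopes make A non-square and measured
    intensities are noisy.
    """
    m = np.asarray(intensities, dtype=float)
    if m.shape[0] != A.n_peaks:
        raise ValueError(
            f"envelope length {m.shape[0]} != correction matrix rows {A.n_peaks}"
        )
    total = m.sum()
    if total <= 0:
        raise EmptyEnvelopeError("empty envelope: all intensities are zero")
    m = m / total
    x, res = nnls(A.matrix, m)
    xs = x.sum()
    if xs <= 0:  # pathological fit; report as fully unlabelled with max residual
        x = np.zeros(A.n_label + 1)
        x[0] = 1.0
    else:
        x = x / xs
    if A.n_label >= 1:
        e = mean_enrichment(x, A.n_label)
    else:
        e = float("nan")
    return CorrectedEnvelope(
        fractions=x,
        residual=float(res),
        enrichment=e,
        labelled_fraction=float(1.0 - x[0]),
        n_label=A.n_label,
    )
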