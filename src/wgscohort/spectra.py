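"""Mutation spectra and signature-weight fitting.

Somatic SNVs are tabulated in the pyrimidine-centered convention: the six
single-nucleotide classes C>A, C>G, C>T, T>A, T>C, T>G, and the 96
trinucleotide classes {5' flank}[ref>alt]{3' flank}.  Mutations reported
with a purine reference are reverse-complemented into the equivalent
pyrimidine class.  A sample's 96-class spectrum is then modeled as a
non-negative mixture of reference signature columns: weights minimize the
squared reconstruction error subject to w >= 0 and sum(w) <= 1, and weights
below a trim threshold are zeroed with the surviving set re-fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "MutationSpectrum",
    "SignatureWeights",
    "single_classes",
    "trinucleotide_classes",
    "build_spectrum",
    "spectrum_from_counts",
    "fit_signature_weights",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PYRIMIDINES = ("C", "T")
_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")


def single_classes() -> List[str]:
    """The six pyrimidine-centered substitution classes."""
    return list(_SUBSTITUTIONS)


def trinucleotide_classes() -> List[str]:
    """The 96 trinucleotide classes, ordered by substitution then flanks."""
    return [f"{f5}[{sub}]{f3}" for sub in _SUBSTITUTIONS for f5 in _BASES for f3 in _BASES]


@dataclass(frozen=True)
class MutationSpectrum:
    """Class labels (6 or 96) with proportions summing to 1."""

    labels: Tuple[str, ...]
    proportions: Tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if len(self.labels) not in (6, 96) or len(p) != len(self.labels):
            raise ValueError("spectrum must have 6 or 96 classes with matching proportions")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be non-negative and sum to 1")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.proportions, dtype=float)


@dataclass(frozen=True)
class SignatureWeights:
    """Non-negative per-signature weights summing to at most 1."""

    names: Tuple[str, ...]
    weights: Tuple[float, ...]

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.names))


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _canonical(ref: str, alt: str, context: str) -> Tuple[str, str, str]:
    """Map a mutation to the pyrimidine-centered class (ref, alt, context)."""
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if ref not in _BASES or alt not in _BASES or any(b not in _BASES for b in context):
        raise ValueError(f"invalid base in mutation {context} {ref}>{alt}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref}")
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} middle base must equal ref {ref!r}")
    if ref in _PYRIMIDINES:
        return ref, alt, context
    return _COMPLEMENT[ref], _COMPLEMENT[alt], _revcomp(context)


def build_spectrum(snvs: Sequence[Tuple[str, str, str]], mode: int = 96) -> MutationSpectrum:
    """Spectrum from (ref, alt, trinucleotide context) triples.

    ``mode`` is 6 (substitution classes) or 96 (trinucleotide classes);
    counts are normalized to proportions.
    """
    if mode not in (6, 96):
        raise ValueError("mode must be 6 or 96")
    labels = single_classes() if mode == 6 else trinucleotide_classes()
    index: Dict[str, int] = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros(len(labels))
    for ref, alt, context in snvs:
        cref, calt, cctx = _canonical(ref, alt, context)
        key = f"{cref}>{calt}" if mode == 6 else f"{cctx[0]}[{cref}>{calt}]{cctx[2]}"
        counts[index[key]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no mutations supplied")
    return MutationSpectrum(tuple(labels), tuple(counts / total))


def spectrum_from_counts(counts: Sequence[float], mode: int = 96) -> MutationSpectrum:
    """Spectrum directly from a class-count vector (e.g. simulated counts)."""
    labels = single_classes() if mode == 6 else trinucleotide_classes()
    c = np.asarray(counts, dtype=float)
    if len(c) != len(labels):
        raise ValueError(f"expected {len(labels)} counts, got {len(c)}")
    total = c.sum()
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    return MutationSpectrum(tuple(labels), tuple(c / total))


def _nnls_simplex(R: np.ndarray, s: np.ndarray) -> np.ndarray:
    """argmin ||R w - s||^2 subject to w >= 0, sum(w) <= 1."""
    S = R.shape[1]
    if S == 1:
        # closed form on [0, 1]
        denom = float(R[:, 0] @ R[:, 0])
        w = float(R[:, 0] @ s) / denom if denom > 0 else 0.0
        return np.array([min(1.0, max(0.0, w))])
    res = optimize.minimize(
        lambda w: 0.5 * np.sum((R @ w - s) ** 2),
        x0=np.full(S, 1.0 / (S + 1)),
        jac=lambda w: R.T @ (R @ w - s),
        bounds=[(0.0, 1.0)] * S,
        constraints=[{"type": "ineq", "fun": lambda w: 1.0 - w.sum(),
                      "jac": lambda w: -np.ones_like(w)}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    return np.clip(res.x, 0.0, None)


def fit_signature_weights(spectrum: MutationSpectrum, reference: pd.DataFrame,
                          trim: float = 0.06) -> SignatureWeights:
    """Non-negative signature weights reconstructing a 96-class spectrum.

    Minimizes the squared error against the reference columns subject to
    w >= 0 and sum(w) <= 1; weights below ``trim`` are zeroed and the
    surviving signatures re-fit.  Deterministic; invariant to reference
    column order up to the fit tolerance.
    """
    if reference.shape[1] < 1:
        raise ValueError("reference must contain at least one signature")
    if reference.shape[0] != 96 or len(spectrum.labels) != 96:
        raise ValueError("signature fitting operates on 96-class spectra")
    ref = reference.reindex(list(spectrum.labels))
    if ref.isna().any().any():
        raise ValueError("reference rows do not cover the 96 trinucleotide classes")
    R = ref.to_numpy(dtype=float)
    s = spectrum.as_array()
    w = _nnls_simplex(R, s)
    keep = w >= trim
    final = np.zeros_like(w)
    if keep.any():
        w_kept = _nnls_simplex(R[:, keep], s)
        # re-fit can push a weight back under the trim threshold; zero those too
        w_kept[w_kept < trim] = 0.0
        final[keep] = w_kept
    return SignatureWeights(tuple(reference.columns), tuple(final))
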