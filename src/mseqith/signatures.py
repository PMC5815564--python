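"""Trinucleotide-context spectra and mutational-signature attribution.

Single-base substitutions are keyed by the 96 classes of (substitution,
5' flank, 3' flank) under the pyrimidine-strand convention: a mutation
reported on the purine strand (reference A or G) is reverse-complemented
before counting. Spectra are decomposed onto a signature catalogue (a
96 x k matrix of per-context probabilities) by nonnegative least squares,
with weights renormalised to a probability vector and the residual
reported as cosine distance — a deterministic solver adequate at per-patient
mutation counts.

The built-in catalogue contains three *synthetic* columns for testing and
simulation only — a flat background, a deamination-clock-like column
concentrated on C>T at NpCpG, and a mismatch-repair-deficiency-like column
— and makes no claim of numerically matching any published catalogue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "CONTEXT_KEYS",
    "SUBSTITUTIONS",
    "ContextSpectrum",
    "SignatureFit",
    "context_key",
    "fold_context",
    "parse_context",
    "count_contexts",
    "builtin_catalogue",
    "read_catalogue",
    "write_catalogue",
    "fit_signatures",
    "attribute_by_clonality",
]

SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Canonical ordering of the 96 context classes:
#: substitution-major, then 5' flank, then 3' flank, each in ACGT order.
CONTEXT_KEYS = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
]
_KEY_INDEX = {k: i for i, k in enumerate(CONTEXT_KEYS)}

#: Minimum mutations for a confident per-set signature fit.
MIN_MUTATIONS = 20


@dataclass
class ContextSpectrum:
    """Counts over the 96 trinucleotide context classes."""

    counts: np.ndarray  # shape (96,), nonnegative
    n_dropped: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def normalized(self) -> np.ndarray:
        t = self.counts.sum()
        if t == 0:
            raise ValueError("zero-total spectrum cannot be normalised")
        return self.counts / t


@dataclass
class SignatureFit:
    """NNLS decomposition of a spectrum onto a signature catalogue."""

    weights: pd.Series  # indexed by signature name; sums to 1
    cosine_distance: float
    n_mutations: int
    low_confidence: bool = False


def context_key(ref: str, alt: str, five: str, three: str) -> str:
    return f"{five}[{ref}>{alt}]{three}"


def parse_context(key: str) -> tuple[str, str, str, str]:
    """Split 'A[C>T]G' into (ref, alt, five, three); raises on malformed keys."""
    try:
        five, rest = key.split("[")
        sub, three = rest.split("]")
        ref, alt = sub.split(">")
    except ValueError as exc:
        raise ValueError(f"malformed context key: {key!r}") from exc
    for b in (five, three, ref, alt):
        if b not in _BASES:
            raise ValueError(f"malformed context key: {key!r}")
    if ref == alt:
        raise ValueError(f"malformed context key (ref == alt): {key!r}")
    return ref, alt, five, three


def fold_context(key: str) -> str:
    """Fold a context key onto the pyrimidine strand.

    Purine-reference keys are reverse-complemented (ref/alt complemented,
    flanks complemented and swapped); pyrimidine keys pass through. The
    operation is an involution up to the canonical strand.
    """
    ref, alt, five, three = parse_context(key)
    if ref in "CT":
        return context_key(ref, alt, five, three)
    return context_key(
        _COMPLEMENT[ref], _COMPLEMENT[alt], _COMPLEMENT[three], _COMPLEMENT[five]
    )


def count_contexts(variants: pd.DataFrame) -> ContextSpectrum:
    """Build a 96-context spectrum from a variant table.

    Uses the ``context`` column (full keys like ``A[C>T]G``); purine-strand
    keys are folded. Empty or malformed contexts are dropped with a warning
    and tallied in ``n_dropped``.
    """
    counts = np.zeros(96)
    dropped = 0
    for raw in variants["context"]:
        if not raw:
            dropped += 1
            continue
        try:
            key = fold_context(raw)
        except ValueError:
            warnings.warn(f"dropping malformed context {raw!r}", RuntimeWarning)
            dropped += 1
            continue
        counts[_KEY_INDEX[key]] += 1
    return ContextSpectrum(counts=counts, n_dropped=dropped)


def builtin_catalogue() -> pd.DataFrame:
    """Small synthetic signature catalogue for tests and simulation.

    Columns: ``flat`` (uniform over 96 classes), ``clock_like`` (C>T
    concentrated at NpCpG, mimicking the shape of a deamination clock
    process), ``mmrd_like`` (C>T and T>C enriched across contexts,
    mimicking the shape of a mismatch-repair-deficiency process). These are
    synthetic stand-ins with the right structure for recovery tests, not
    reproductions of any published signature.
    """
    flat = np.full(96, 1.0 / 96)

    clock = np.full(96, 0.2 / 96)
    npcg = [_KEY_INDEX[context_key("C", "T", five, "G")] for five in _BASES]
    clock[npcg] += 0.8 / len(npcg)

    mmrd = np.full(96, 0.15 / 96)
    ct_a = [
        _KEY_INDEX[context_key("C", "T", five, three)]
        for five in "AG"
        for three in "ACT"
    ]
    tc = [
        _KEY_INDEX[context_key("T", "C", five, three)]
        for five in _BASES
        for three in "AG"
    ]
    mmrd[ct_a] += 0.55 / len(ct_a)
    mmrd[tc] += 0.30 / len(tc)

    cat = pd.DataFrame(
        {"flat": flat, "clock_like": clock, "mmrd_like": mmrd}, index=CONTEXT_KEYS
    )
    return cat / cat.sum(axis=0)


def read_catalogue(path) -> pd.DataFrame:
    """Read a catalogue TSV (96 rows keyed by context, one column per signature)."""
    cat = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CONTEXT_KEYS) - set(cat.index)
    if missing:
        raise ValueError(f"catalogue missing {len(missing)} context rows")
    cat = cat.loc[CONTEXT_KEYS]
    if (cat.values < 0).any():
        raise ValueError("catalogue probabilities must be nonnegative")
    sums = cat.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("each catalogue column must sum to 1")
    return cat


def write_catalogue(path, catalogue: pd.DataFrame) -> None:
    catalogue.to_csv(path, sep="\t", index_label="context")


def fit_signatures(
    spectrum: ContextSpectrum | np.ndarray, catalogue: pd.DataFrame
) -> SignatureFit:
    """Nonnegative least-squares fit of a spectrum onto the catalogue.

    The observed spectrum is normalised to frequencies, projected onto the
    catalogue columns by NNLS, and the resulting weights renormalised to sum
    to 1. Reconstruction error is the cosine distance between the observed
    and reconstructed spectra.
    """
    if isinstance(spectrum, ContextSpectrum):
        counts = spectrum.counts
    else:
        counts = np.asarray(spectrum, dtype=float)
    if counts.shape != (96,):
        raise ValueError("spectrum must have 96 context classes")
    total = counts.sum()
    if total <= 0:
        raise ValueError("zero-total spectrum cannot be fitted")
    target = counts / total
    A = catalogue.to_numpy()
    w, _ = nnls(A, target)
    if w.sum() <= 0:
        raise ValueError("NNLS returned an all-zero solution")
    weights = w / w.sum()
    recon = A @ weights
    denom = np.linalg.norm(target) * np.linalg.norm(recon)
    cos = float(target @ recon / denom) if denom > 0 else 0.0
    return SignatureFit(
        weights=pd.Series(weights, index=catalogue.columns),
        cosine_distance=1.0 - cos,
        n_mutations=int(total),
        low_confidence=total < MIN_MUTATIONS,
    )


def attribute_by_clonality(
    classified_variants: pd.DataFrame,
    catalogue: pd.DataFrame,
    *,
    min_mutations: int = MIN_MUTATIONS,
) -> dict[str, SignatureFit | None]:
    """Independent signature fits for ubiquitous vs non-ubiquitous mutations.

    ``classified_variants`` is the one-row-per-mutation table carrying a
    ``presence_class`` column. Sets below ``min_mutations`` are fitted but
    flagged low-confidence; empty sets yield None.
    """
    out: dict[str, SignatureFit | None] = {}
    masks = {
        "ubiquitous": classified_variants["presence_class"] == "ubiquitous",
        "non_ubiquitous": classified_variants["presence_class"] != "ubiquitous",
    }
    for name, mask in masks.items():
        subset = classified_variants[mask]
        spectrum = count_contexts(subset)
        if spectrum.total == 0:
            out[name] = None
            continue
        fit = fit_signatures(spectrum, catalogue)
        fit.low_confidence = spectrum.total < min_mutations
        out[name] = fit
    return out
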