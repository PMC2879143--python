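"""Length-bias correction and cross-sample normalization of spectral counts.

Spectral counting is a semi-quantitative label-free measure: the number of
MS/MS spectra mapped to a protein tracks its abundance, but larger proteins
yield more observable tryptic peptides and therefore accumulate more counts.
The correction divides each protein's counts by its number of *expected
tryptic peptides* — the distinct peptides an in-silico trypsin digest produces
within observable length bounds. Residual sample-to-sample differences
(loading, instrument drift) are then removed with a lowess fit of each
sample's log-ratio against a pseudo-reference, the standard MA-normalization
scheme for expression matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import parser as _pyt_parser
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

logger = logging.getLogger(__name__)

#: 20 standard residues plus X (unknown; never a cleavage site).
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Trypsin: cleave C-terminal to K or R, except when followed by P.
TRYPSIN_RULE = r"[KR](?!P)"

CONDITIONS = ("disease", "control")


class ProtmapError(Exception):
    """Base class for errors raised by this package."""


class InputError(ProtmapError):
    """Malformed or inconsistent user input."""


@dataclass(frozen=True)
class DigestionParams:
    """In-silico digestion settings for expected-peptide computation.

    The length window restricts counting to peptides an LC-MS/MS experiment
    can plausibly observe. Defaults: 6–35 residues, no missed cleavages.
    """

    min_peptide_length: int = 6
    max_peptide_length: int = 35
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.min_peptide_length < 1:
            raise InputError("min_peptide_length must be positive")
        if self.min_peptide_length > self.max_peptide_length:
            raise InputError(
                f"min_peptide_length {self.min_peptide_length} exceeds "
                f"max_peptide_length {self.max_peptide_length}"
            )
        if self.missed_cleavages < 0:
            raise InputError("missed_cleavages must be nonnegative")


@dataclass
class CountMatrix:
    """Protein-by-sample abundance table with its sample design.

    ``values`` is a proteins x samples DataFrame (raw inputs are integer
    spectral counts; normalized values are real). ``design`` is indexed by
    sample id with columns ``condition`` (disease/control) and ``stage``.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise InputError(f"duplicate protein ids: {list(dups)[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise InputError(f"duplicate sample ids: {list(dups)[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise InputError("count matrix contains negative values")
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise InputError(f"samples without design record: {sorted(missing)}")
        bad = set(self.design["condition"]) - set(CONDITIONS)
        if bad:
            raise InputError(
                f"unknown conditions {sorted(bad)}; expected one of {CONDITIONS}"
            )
        self.design = self.design.loc[self.values.columns]

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def stages(self) -> list[str]:
        return list(dict.fromkeys(self.design["stage"]))

    def samples_for(self, stage: str, condition: str) -> list[str]:
        d = self.design
        mask = (d["stage"] == stage) & (d["condition"] == condition)
        return list(d.index[mask])

    def copy_with(self, values: pd.DataFrame) -> "CountMatrix":
        return CountMatrix(values=values, design=self.design.copy())


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise InputError("empty protein sequence")
    for pos, ch in enumerate(sequence, start=1):
        if ch not in VALID_RESIDUES:
            raise InputError(
                f"invalid residue {ch!r} at position {pos} in sequence"
            )


def expected_peptide_count(sequence: str, params: DigestionParams | None = None) -> int:
    """Number of distinct in-silico tryptic peptides within the length window.

    Trypsin cleaves C-terminal to K/R unless the next residue is P. With
    ``missed_cleavages`` = m, runs of up to m+1 consecutive fragments count as
    peptides. Duplicate peptide sequences are counted once.
    """
    params = params or DigestionParams()
    _validate_sequence(sequence)
    peptides = _pyt_parser.cleave(
        sequence, TRYPSIN_RULE, missed_cleavages=params.missed_cleavages
    )
    lo, hi = params.min_peptide_length, params.max_peptide_length
    return sum(1 for p in peptides if lo <= len(p) <= hi)


def length_normalize(
    counts: CountMatrix,
    seqs: dict[str, str] | None = None,
    params: DigestionParams | None = None,
    expected_peptides: dict[str, int] | pd.Series | None = None,
) -> CountMatrix:
    """Divide each protein's counts by its expected tryptic-peptide number.

    ``expected_peptides`` may supply precomputed values (takes precedence over
    sequences). A protein whose digest yields no peptide inside the length
    window keeps a divisor of 1 so it is retained; this is logged.
    """
    params = params or DigestionParams()
    if expected_peptides is not None:
        exp = pd.Series(dict(expected_peptides), dtype=float)
    else:
        exp = pd.Series(dtype=float)

    missing = [p for p in counts.protein_ids if p not in exp.index]
    if missing:
        if seqs is None:
            raise InputError(
                f"no sequence or expected-peptide value for proteins: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        unseq = [p for p in missing if p not in seqs]
        if unseq:
            raise InputError(
                f"missing sequences for proteins: {unseq[:10]}"
                + ("..." if len(unseq) > 10 else "")
            )
        computed = {p: expected_peptide_count(seqs[p], params) for p in missing}
        exp = pd.concat([exp, pd.Series(computed, dtype=float)])

    exp = exp.loc[counts.protein_ids]
    n_zero = int((exp == 0).sum())
    if n_zero:
        logger.warning(
            "%d protein(s) yield no in-window tryptic peptide; "
            "expected-peptide count floored at 1",
            n_zero,
        )
        exp = exp.clip(lower=1.0)
    normalized = counts.values.div(exp, axis=0)
    return counts.copy_with(normalized)


def lowess_normalize(counts: CountMatrix, span: float = 0.4) -> CountMatrix:
    """Remove per-sample intensity-dependent bias by lowess MA regression.

    Internally on log2(value + 0.5). The pseudo-reference is the per-protein
    mean of log2 values across samples (a geometric mean on the pseudocounted
    scale). For each sample, M = log2(sample) - log2(reference) is regressed
    on A = (log2(sample) + log2(reference)) / 2 with a lowess smoother of the
    given span, and the fitted trend is subtracted. Zero entries stay zero.
    """
    if not 0 < span <= 1:
        raise InputError(f"span must be in (0, 1], got {span}")
    if len(counts.sample_ids) < 2:
        raise InputError("lowess normalization needs at least 2 samples")

    raw = counts.values.to_numpy(dtype=float)
    log_vals = np.log2(raw + 0.5)
    ref = log_vals.mean(axis=1)

    out = np.empty_like(log_vals)
    for j in range(log_vals.shape[1]):
        m = log_vals[:, j] - ref
        a = (log_vals[:, j] + ref) / 2.0
        fitted = _sm_lowess(m, a, frac=span, return_sorted=False)
        # A flat sample (constant A) makes lowess return NaN; no trend to remove.
        fitted = np.where(np.isfinite(fitted), fitted, 0.0)
        out[:, j] = log_vals[:, j] - fitted

    adjusted = np.clip(np.exp2(out) - 0.5, 0.0, None)
    adjusted[raw == 0] = 0.0
    values = pd.DataFrame(
        adjusted, index=counts.values.index, columns=counts.values.columns
    )
    return counts.copy_with(values)
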