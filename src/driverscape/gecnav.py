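"""Expression-based validation of copy-number calls (GECNAV).

Thresholded copy-number calls are coarse: an amplified segment drags along
many genes whose dosage never reaches the transcriptome.  This module encodes
each gene's expression relative to its cross-patient median into five levels
and keeps a CNA call only when the expression level agrees in sign, replacing
the call with the (often more conservative) expression level.

Encoding of x against the per-gene median m:

    x < 0.05*m            -> -2      (effectively silenced)
    0.05*m <= x < 0.75*m  -> -1      (reduced)
    0.75*m <= x <= 1.25*m ->  0      (neutral band)
    1.25*m < x <= 1.75*m  ->  1      (elevated)
    x > 1.75*m            ->  2      (strongly over-expressed)

The band edges follow the published thresholds; boundary membership is chosen
so the five bands partition the axis totally and deterministically.  A gene
with median 0 is degenerate and encodes to 0 everywhere.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_filtering import GeneSampleMatrix

logger = logging.getLogger("driverscape")

EXPRESSION_CODES = (-2, -1, 0, 1, 2)


def encode_relative_expression(x, m):
    """Encode expression value(s) ``x`` against per-gene median ``m``.

    Scalar or array-like; NaN inputs stay NaN.  ``m == 0`` encodes to 0.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    code = np.zeros(np.broadcast(x, m).shape, dtype=float)
    with np.errstate(invalid="ignore"):
        code = np.where(x < 0.05 * m, -2.0, code)
        code = np.where((x >= 0.05 * m) & (x < 0.75 * m), -1.0, code)
        code = np.where((x > 1.25 * m) & (x <= 1.75 * m), 1.0, code)
        code = np.where(x > 1.75 * m, 2.0, code)
    code = np.where(m == 0, 0.0, code)  # degenerate gene
    code = np.where(np.isnan(x) | np.isnan(m), np.nan, code)
    if code.ndim == 0:
        return float(code)
    return code


def encode_matrix(expr: GeneSampleMatrix) -> GeneSampleMatrix:
    """Encode a full expression matrix; medians are per gene across patients.

    Medians ignore missing cells.  All-missing rows stay missing and are
    logged; zero-median rows encode to 0 (degenerate, logged).
    """
    if expr.values.empty:
        raise ValueError("empty expression matrix")
    medians = expr.values.median(axis=1, skipna=True)
    n_all_missing = int(medians.isna().sum())
    if n_all_missing:
        logger.info("encode_matrix: %d genes have no expression values", n_all_missing)
    n_zero = int((medians == 0).sum())
    if n_zero:
        logger.info("encode_matrix: %d genes have zero median expression", n_zero)
    coded = encode_relative_expression(
        expr.values.to_numpy(dtype=float), medians.to_numpy()[:, None])
    return GeneSampleMatrix(
        pd.DataFrame(coded, index=expr.values.index, columns=expr.values.columns),
        expr.hugo,
    )


def validate_cna(
    cna: GeneSampleMatrix,
    expr_codes: GeneSampleMatrix,
    mirna_codes: GeneSampleMatrix | None = None,
) -> GeneSampleMatrix:
    """Replace sign-concordant CNA calls with the expression code, else zero.

    Per cell: a nonzero CNA call whose sign matches a nonzero expression code
    becomes that code; a nonzero call with a discordant or zero code becomes
    0; a zero call stays 0.  Genes absent from both expression matrices (and
    cells with no expression value, e.g. samples not profiled) pass through
    unchanged.  Genes are matched by Entrez ID; a gene found in the miRNA
    code matrix is routed there, otherwise to the mRNA matrix.
    """
    code_sources = [m for m in (mirna_codes, expr_codes) if m is not None]

    codes = pd.DataFrame(np.nan, index=cna.values.index, columns=cna.values.columns)
    covered = pd.Series(False, index=cna.values.index)
    for src in code_sources:
        hit = cna.values.index.intersection(src.values.index).difference(
            covered.index[covered])
        if len(hit) == 0:
            continue
        covered.loc[hit] = True
        aligned = src.values.reindex(index=hit, columns=cna.values.columns)
        codes.loc[hit] = aligned.to_numpy()

    n_uncovered = int((~covered).sum())
    if n_uncovered:
        logger.info("validate_cna: %d genes lack expression rows; calls passed "
                    "through", n_uncovered)

    c = cna.values.to_numpy(dtype=float)
    e = codes.to_numpy(dtype=float)
    concordant = (np.sign(c) == np.sign(e)) & (e != 0)
    out = np.where(c == 0, 0.0, np.where(np.isnan(e), c, np.where(concordant, e, 0.0)))
    out = np.where(np.isnan(c), np.nan, out)
    return GeneSampleMatrix(
        pd.DataFrame(out, index=cna.values.index, columns=cna.values.columns),
        cna.hugo,
    )
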