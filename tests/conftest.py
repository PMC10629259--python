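import numpy as np
import pandas as pd
import pytest

from lfqstats.io import (
    BIOREPLICATE,
    CANONICAL_COLUMNS,
    CONDITION,
    FRAGMENT_ION,
    INTENSITY,
    LABEL,
    LOG_INTENSITY,
    PEPTIDE,
    PRECURSOR_CHARGE,
    PRODUCT_CHARGE,
    PROTEIN,
    RUN,
)


def make_canonical(cells, conditions=None):
    """Build a canonical frame from (protein, peptide, run, intensity) tuples.

    ``conditions`` maps run -> (condition, bioreplicate); defaults to one
    condition per run prefix before the last underscore-free token.
    """
    rows = []
    for protein, peptide, run, intensity in cells:
        cond, biorep = (conditions or {}).get(run, (f"C_{run}", f"S_{run}"))
        rows.append(
            {
                PROTEIN: protein,
                PEPTIDE: peptide,
                PRECURSOR_CHARGE: "2",
                FRAGMENT_ION: "NA",
                PRODUCT_CHARGE: "NA",
                LABEL: "L",
                CONDITION: cond,
                BIOREPLICATE: biorep,
                RUN: run,
                INTENSITY: intensity,
            }
        )
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def make_log_frame(matrix, proteins=None, run_names=None, status=None):
    """Long frame with LogIntensity from a feature-by-run array (NaN = missing)."""
    from lfqstats.censoring import CENSORED, OBSERVED, STATUS

    matrix = np.asarray(matrix, dtype=float)
    nf, nr = matrix.shape
    runs = run_names or [f"r{k:02d}" for k in range(nr)]
    rows = []
    for l in range(nf):
        for k in range(nr):
            val = matrix[l, k]
            st = OBSERVED if np.isfinite(val) else CENSORED
            if status is not None:
                st = status[l][k]
            rows.append(
                {
                    PROTEIN: (proteins or ["P"] * nf)[l],
                    PEPTIDE: f"pep{l}",
                    PRECURSOR_CHARGE: "2",
                    FRAGMENT_ION: "NA",
                    PRODUCT_CHARGE: "NA",
                    LABEL: "L",
                    CONDITION: "C1",
                    BIOREPLICATE: "S1",
                    RUN: runs[k],
                    LOG_INTENSITY: val if np.isfinite(val) else np.nan,
                    STATUS: st,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
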