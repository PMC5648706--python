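"""Synthetic patient cohorts calibrated to the published group summaries.

The study's raw patient-level expression values were never deposited; what is
printed is, per gene, per instrument and per group (PJI / non-PJI), the group
mean with a 95% confidence interval of the mean and the group size. This
module turns each such summary into a log-normal distribution matched in mean
and variance, and draws whole cohorts from those distributions so that every
downstream stage (feature selection, ensemble training, diagnostics, graphs)
can be exercised and tested end to end.

Why log-normal: relative expression is strictly positive, spans orders of
magnitude between patients, and the printed means sit far above the centers
of their CIs — the signature of a right-skewed positive distribution. The
log-normal is the simplest such family fixed by two moments.

Moment matching: the CI is read as the normal-theory interval
``mean +/- 1.96 * SD / sqrt(n)``, so ``SD = sqrt(n) * width / (2 * 1.96)``.
With ``CV = SD / mean`` the log-normal parameters are
``sigma^2 = ln(1 + CV^2)`` and ``mu = ln(mean) - sigma^2 / 2``, which makes
the analytic expectation ``exp(mu + sigma^2/2)`` equal the printed mean
exactly. A negative printed CI lower bound (possible under the normal
approximation, e.g. IL1B in non-PJI tissue) only affects the width, never
validity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import NON_PJI, PJI, CohortTable


class CalibrationError(ValueError):
    """A requested gene/group has no calibration."""


@dataclass(frozen=True)
class GroupCalibration:
    """Printed summary of one gene in one patient group on one instrument.

    mean, ci_low, ci_high are in relative-expression units (vs HPRT1);
    the CI is the 95% CI of the group mean; n is the group size.
    """

    gene: str
    group: str
    mean: float
    ci_low: float
    ci_high: float
    n: int
    instrument: str

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError(f"{self.gene}/{self.group}: mean must be positive")
        if not self.ci_low < self.ci_high:
            raise ValueError(f"{self.gene}/{self.group}: ci_low must be < ci_high")
        if self.n <= 1:
            raise ValueError(f"{self.gene}/{self.group}: n must exceed 1")

    def lognormal_params(self) -> tuple[float, float]:
        return lognormal_params_from_mean_ci(self.mean, self.ci_low, self.ci_high, self.n)


def lognormal_params_from_mean_ci(
    mean: float, ci_low: float, ci_high: float, n: int
) -> tuple[float, float]:
    """Log-normal (mu, sigma) whose expectation equals *mean* and whose
    variance matches the SD implied by a normal-theory 95% CI of the mean.

    Returns sigma = 0 (degenerate point mass at *mean*) with a warning when
    the CI has zero width.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if ci_high < ci_low:
        raise ValueError("ci_high must be >= ci_low")
    if n <= 1:
        raise ValueError("n must exceed 1")
    width = ci_high - ci_low
    if width == 0:
        warnings.warn("degenerate CI (zero width): sigma set to 0", stacklevel=2)
        return math.log(mean), 0.0
    sd = math.sqrt(n) * width / (2 * 1.96)
    cv = sd / mean
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2
    return mu, math.sqrt(sigma2)


# --------------------------------------------------------------------------
# Built-in calibrations: per-gene group means (95% CI of the mean) relative
# to HPRT1, for the 38/38 RotorGene Q cohort and the 23/25 Xxpress cohort.
# CRP, TLR6, TLR10 and DEFB4A were not assayed on the Xxpress instrument.
# --------------------------------------------------------------------------

def _table(instrument: str, n_pji: int, n_non: int, rows) -> dict[tuple[str, str], GroupCalibration]:
    out = {}
    for gene, pji, non in rows:
        out[gene, PJI] = GroupCalibration(gene, PJI, *pji, n_pji, instrument)
        out[gene, NON_PJI] = GroupCalibration(gene, NON_PJI, *non, n_non, instrument)
    return out


TABLE1_ROTORGENE: dict[tuple[str, str], GroupCalibration] = _table(
    "rotorgene", 38, 38,
    [
        ("DEFA1", (1.021, 0.001, 2.042), (0.035, 0.017, 0.053)),
        ("IL1B", (4.361, 0.717, 8.006), (0.201, 0.093, 0.309)),
        ("LTF", (5.599, 0.228, 13.710), (0.162, 0.095, 0.228)),
        ("TLR1", (1.856, 1.452, 2.261), (1.563, 0.970, 2.156)),
        ("BPI", (0.445, 0.039, 0.964), (0.041, 0.025, 0.057)),
        ("IFNG", (9.146, 2.438, 15.850), (3.690, 2.230, 5.150)),
        ("TLR2", (3.876, 2.276, 5.476), (2.005, 1.399, 2.610)),
        ("TLR4", (2.515, 1.817, 3.213), (3.060, 2.380, 3.740)),
        ("CRP", (3.912, 1.151, 6.673), (5.079, 2.781, 7.377)),
        ("TLR6", (4.121, 2.748, 5.495), (3.045, 2.387, 3.703)),
        ("TLR10", (3.154, 1.504, 4.804), (3.164, 2.087, 4.242)),
        ("DEFB4A", (12.350, 3.624, 21.080), (4.601, 2.397, 6.806)),
    ],
)

TABLE1_XXPRESS: dict[tuple[str, str], GroupCalibration] = _table(
    "xxpress", 23, 25,
    [
        ("DEFA1", (19.650, 0.278, 57.030), (0.057, 0.013, 0.102)),
        ("IL1B", (0.637, 0.042, 1.585), (0.013, -0.0001, 0.025)),
        ("LTF", (7.606, 0.638, 18.380), (0.397, 0.183, 0.612)),
        ("TLR1", (2.728, 1.313, 4.143), (0.927, 0.320, 1.535)),
        ("BPI", (1.524, 0.177, 3.559), (0.181, 0.020, 0.341)),
        ("IFNG", (0.954, 0.405, 1.503), (1.681, 0.405, 2.958)),
        ("TLR2", (1.680, 0.988, 2.373), (0.625, 0.206, 1.043)),
        ("TLR4", (7.549, 4.679, 10.420), (5.651, 3.316, 7.986)),
    ],
)

#: Genes absent per instrument (no calibration exists for them there).
MISSING_GENES = {
    "rotorgene": frozenset(),
    "xxpress": frozenset({"CRP", "TLR6", "TLR10", "DEFB4A"}),
}

#: Named built-in calibration sets addressable from configs and the CLI.
CALIBRATION_SETS: dict[str, dict[tuple[str, str], GroupCalibration]] = {
    "table1_rotorgene": TABLE1_ROTORGENE,
    "table1_xxpress": TABLE1_XXPRESS,
}

#: Default cohort sizes per calibration set (the published column headers).
DEFAULT_SIZES = {"table1_rotorgene": (38, 38), "table1_xxpress": (23, 25)}


@dataclass
class CohortSpec:
    """Everything needed to draw one synthetic cohort reproducibly.

    correlation is a common pairwise correlation applied between genes on the
    log scale (a sensitivity knob for co-elevated infection markers); the
    default 0 draws genes independently.
    """

    calibrations: dict[tuple[str, str], GroupCalibration]
    n_pji: int
    n_non: int
    seed: int = 0
    missing_genes: frozenset[str] = frozenset()
    correlation: float = 0.0
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.genes:
            self.genes = tuple(dict.fromkeys(g for g, _ in self.calibrations))
        for gene in self.genes:
            if gene in self.missing_genes:
                continue
            for group in (PJI, NON_PJI):
                if (gene, group) not in self.calibrations:
                    raise CalibrationError(f"no calibration for {gene}/{group}")
        if not -1.0 < self.correlation < 1.0:
            raise ValueError("correlation must lie in (-1, 1)")

    @classmethod
    def from_named(
        cls,
        name: str,
        genes=None,
        n_pji: int | None = None,
        n_non: int | None = None,
        seed: int = 0,
        correlation: float = 0.0,
    ) -> "CohortSpec":
        """Build a spec from a named built-in calibration set, e.g.
        ``table1_xxpress`` (23/25) or ``table1_rotorgene`` (38/38)."""
        if name not in CALIBRATION_SETS:
            raise CalibrationError(
                f"unknown calibration set {name!r}; available: {sorted(CALIBRATION_SETS)}"
            )
        cal = CALIBRATION_SETS[name]
        d_pji, d_non = DEFAULT_SIZES[name]
        available = tuple(dict.fromkeys(g for g, _ in cal))
        return cls(
            calibrations=cal,
            n_pji=d_pji if n_pji is None else n_pji,
            n_non=d_non if n_non is None else n_non,
            seed=seed,
            correlation=correlation,
            genes=tuple(genes) if genes else available,
        )


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a cohort from per-gene, per-group calibrated log-normals.

    Patients are drawn independently; genes are independent on the log scale
    unless ``spec.correlation`` is nonzero, in which case log values share a
    common equicorrelation structure. Cells of genes in ``spec.missing_genes``
    are marked missing. Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    present = [g for g in spec.genes if g not in spec.missing_genes]
    rows: list[np.ndarray] = []
    labels: list[str] = []
    for group, n in ((PJI, spec.n_pji), (NON_PJI, spec.n_non)):
        mus = np.array([spec.calibrations[g, group].lognormal_params()[0] for g in present])
        sigmas = np.array([spec.calibrations[g, group].lognormal_params()[1] for g in present])
        if spec.correlation and len(present) > 1:
            corr = np.full((len(present),) * 2, spec.correlation)
            np.fill_diagonal(corr, 1.0)
            z = rng.multivariate_normal(np.zeros(len(present)), corr, size=n,
                                        method="cholesky")
        else:
            z = rng.standard_normal((n, len(present)))
        rows.append(np.exp(mus + sigmas * z))
        labels.extend([group] * n)
    data = np.vstack(rows) if rows else np.empty((0, len(present)))
    index = [f"S{i + 1:05d}" for i in range(len(labels))]
    values = pd.DataFrame(data, index=index, columns=present)
    for gene in spec.genes:
        if gene in spec.missing_genes:
            values[gene] = np.nan
    values = values[list(spec.genes)]
    return CohortTable(values, pd.Series(labels, index=index), source="synthetic")
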