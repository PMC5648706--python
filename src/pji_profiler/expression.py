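"""Relative qRT-PCR quantification and cohort tables.

Implements the classic 2^-ddCt relative quantification of target-gene mRNA
against the housekeeping gene HPRT1 and a universal-reference-RNA calibrator,
plus the patient x gene relative-expression table (:class:`CohortTable`) that
every downstream stage (synthetic generation, feature selection, ensemble
classification, diagnostics, similarity graphs) exchanges.

Ct values live on the PCR cycle scale: one cycle fewer means twice as much
template at amplification efficiency 2, which is what 2^-ddCt assumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Assay constants
# --------------------------------------------------------------------------

#: Housekeeping gene every target is normalized to.
REFERENCE_GENE = "HPRT1"

#: Number of PCR cycles in a run; a determined Ct cannot exceed this.
MAX_CYCLES = 35.0

#: Class labels used throughout the package. PJI is the positive class.
PJI = "PJI"
NON_PJI = "non-PJI"
LABELS = (PJI, NON_PJI)

#: Assay metadata: gene -> (RefSeq accession, forward primer, reverse primer,
#: amplicon length in bp). Kept as reference constants; the package never
#: computes with the sequences.
PRIMERS: Mapping[str, tuple[str, str, str, int]] = {
    "HPRT1": ("NM_000194.2", "TGATAGATCCATTCCTATGACTGTAGA", "CAAGACATTCTTTCCAGTTAAAGTTG", 127),
    "DEFA1": ("NM_004084.3", "CCTGCCTAGCTAGAGGATCTGT", "CATCAGCTCTTGCCTGGAGT", 114),
    "DEFB4A": ("NM_004942.3", "GAGGGAGCCCTTTTCTGAATC", "GTCTCCCTGGAACAAAATGC", 89),
    "LTF": ("NM_002343.5", "CTAATCTGAAAAAGTGCTCAACCTC", "GCCATCTTCTTCGGTTTTACTTC", 78),
    "BPI": ("NM_001725.2", "ACGTGCACATCTCAAAGAGC", "CGAAGCGCAGACTCAATTTT", 73),
    "IL1B": ("NM_000576.2", "CTAAACAGATGAAGTGCTCC", "GGTCATTCTCCTGGAAGG", 183),
    "IFNG": ("NM_000619.2", "GGCATTTTGAAGAATTGGAAAG", "TTTGGATGCTCTGGTCATCTT", 112),
    "CRP": ("NM_000567.2", "GAATTCAGGCCCTTGTATCACT", "ACACAAAAGCCTTCCTCGAC", 124),
    "TLR1": ("NM_003263.3", "CCCTACAAAAGGAATCTGTATC", "TGCTAGTCATTTTGGAACAC", 89),
    "TLR2": ("NM_003264.4", "CTTTCAACTGGTAGTTGTGG", "GGAATGGAGTTTAAAGATCCTG", 176),
    "TLR4": ("NM_138557.2", "GATTTATCCAGGTGTGAAATCC", "TATTAAGGTAGAGAGGTGGC", 75),
    "TLR6": ("NM_006068.4", "CTGCCCAAGATTCAGGAGTG", "CCATTGCCTTACAACAAAGTTCT", 63),
    "TLR10": ("NM_030956.3", "AGATTGCTTTTGCCACCAAC", "TCTCACATCTCCTTTTGATAGCC", 114),
}

#: All assayed gene symbols (12 candidates + the housekeeping gene).
ASSAYED_GENES = tuple(PRIMERS)

#: The 12 candidate biomarker genes (reference gene excluded).
CANDIDATE_GENES = tuple(g for g in ASSAYED_GENES if g != REFERENCE_GENE)

WELL_ROLES = ("sample", "calibrator", "ntc")


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------

class CohortFormatError(ValueError):
    """Malformed cohort or Ct table (bad header, unknown gene, missing label)."""


class CohortValidationError(ValueError):
    """Structurally valid table whose values violate an invariant."""


class QuantificationError(ValueError):
    """A Ct required for 2^-ddCt is undetermined or absent."""


class ContaminationWarning(UserWarning):
    """A no-template control amplified below the contamination cutoff."""


# --------------------------------------------------------------------------
# Ct records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: a Ct value (or None if undetermined) for one gene.

    Parameters
    ----------
    sample_id : str
        Patient/sample identifier; for calibrator and NTC wells a run-level id.
    gene : str
        Gene symbol, one of :data:`ASSAYED_GENES`.
    ct : float or None
        Threshold cycle; ``None`` means the well never crossed threshold
        within the run. A determined Ct must lie in ``(0, MAX_CYCLES]``.
    well_role : str
        ``"sample"``, ``"calibrator"`` or ``"ntc"`` (no-template control).
    """

    sample_id: str
    gene: str
    ct: float | None
    well_role: str = "sample"

    def __post_init__(self) -> None:
        if self.gene not in ASSAYED_GENES:
            raise CohortFormatError(f"unknown gene symbol: {self.gene!r}")
        if self.well_role not in WELL_ROLES:
            raise CohortFormatError(f"unknown well role: {self.well_role!r}")
        if self.ct is not None:
            ct = float(self.ct)
            if not np.isfinite(ct) or not (0.0 < ct <= MAX_CYCLES):
                raise CohortValidationError(
                    f"Ct {self.ct!r} outside (0, {MAX_CYCLES:g}] for "
                    f"{self.gene}/{self.sample_id}"
                )


def load_ct_table(path: str | Path, dialect: str = "csv") -> list[CtRecord]:
    """Read a Ct table (columns sample_id, gene, ct, well_role).

    Blank or ``NA``/``Undetermined`` ct cells become undetermined wells.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise CohortFormatError(f"unknown dialect: {dialect!r}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"sample_id", "gene", "ct", "well_role"}
    if not required.issubset(df.columns):
        raise CohortFormatError(
            f"Ct table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    records = []
    for row in df.itertuples(index=False):
        raw = row.ct.strip()
        ct = None if raw in ("", "NA", "Undetermined") else float(raw)
        records.append(CtRecord(row.sample_id, row.gene, ct, row.well_role))
    return records


def relative_expression(
    cts: Iterable[CtRecord],
    gene: str,
    sample_id: str,
    reference_gene: str = REFERENCE_GENE,
    ntc_cutoff: float = MAX_CYCLES,
) -> float:
    """Relative expression of *gene* in *sample_id* by the 2^-ddCt method.

    ddCt = (Ct_gene,sample - Ct_ref,sample)
         - (mean Ct_gene,calibrator - mean Ct_ref,calibrator)

    Calibrator wells (the universal reference RNA, run in triplicate) are
    averaged on the Ct scale. Amplification efficiency is fixed at 2, so the
    result is ``2 ** -ddCt``: strictly positive, equal to 1 when sample and
    calibrator have identical gene/reference differences.

    Any determined Ct in a no-template control below ``ntc_cutoff`` raises a
    :class:`ContaminationWarning` (the result is still returned).

    Raises
    ------
    QuantificationError
        If a required well is missing or undetermined.
    """
    records = list(cts)

    def _wells(g: str, role: str, sid: str | None = None) -> list[CtRecord]:
        return [
            r for r in records
            if r.gene == g and r.well_role == role
            and (sid is None or r.sample_id == sid)
        ]

    def _one(g: str, sid: str) -> float:
        wells = _wells(g, "sample", sid)
        if not wells:
            raise QuantificationError(f"no sample well for {g}/{sid}")
        cts_ = [w.ct for w in wells]
        if any(c is None for c in cts_):
            raise QuantificationError(f"undetermined Ct in sample well {g}/{sid}")
        return float(np.mean(cts_))

    def _cal(g: str) -> float:
        wells = _wells(g, "calibrator")
        if not wells:
            raise QuantificationError(f"no calibrator well for {g}")
        cts_ = [w.ct for w in wells]
        if any(c is None for c in cts_):
            raise QuantificationError(f"undetermined Ct in calibrator well for {g}")
        return float(np.mean(cts_))

    for r in records:
        if r.well_role == "ntc" and r.ct is not None and r.ct < ntc_cutoff:
            warnings.warn(
                f"NTC for {r.gene} amplified at Ct {r.ct:g} (< {ntc_cutoff:g})",
                ContaminationWarning,
                stacklevel=2,
            )

    ddct = (_one(gene, sample_id) - _one(reference_gene, sample_id)) - (
        _cal(gene) - _cal(reference_gene)
    )
    return float(2.0 ** -ddct)


# --------------------------------------------------------------------------
# Cohort tables
# --------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Patient x gene relative-expression matrix with class labels.

    ``values`` is a float DataFrame indexed by patient id with gene-symbol
    columns; missing measurements are NaN (never 0 — a relative expression of
    0 would be a claim about the biology, missing is absence of a claim).
    ``labels`` is a Series over the same index with values ``"PJI"`` /
    ``"non-PJI"``.
    """

    values: pd.DataFrame
    labels: pd.Series
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str).rename("patient_id")
        self.labels = self.labels.reindex(self.values.index)
        if self.labels.isna().any():
            missing = self.labels.index[self.labels.isna()].tolist()
            raise CohortValidationError(f"patients without a label: {missing}")
        bad_labels = set(self.labels) - set(LABELS)
        if bad_labels:
            raise CohortValidationError(f"unknown labels: {sorted(bad_labels)}")
        unknown = [g for g in self.values.columns if g not in ASSAYED_GENES]
        if unknown:
            raise CohortFormatError(f"unknown gene symbols: {unknown}")
        if (self.values.to_numpy() < 0).any():
            raise CohortValidationError("negative relative expression value")
        if self.source not in ("rotorgene", "xxpress", "synthetic"):
            raise CohortValidationError(f"unknown source: {self.source!r}")

    # -- conveniences -----------------------------------------------------

    @property
    def patients(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_pji(self) -> int:
        return int((self.labels == PJI).sum())

    @property
    def n_non(self) -> int:
        return int((self.labels == NON_PJI).sum())

    def y(self) -> np.ndarray:
        """Binary label vector: 1 = PJI (infection), 0 = non-PJI."""
        return (self.labels == PJI).to_numpy(dtype=int)

    def complete_cases(self, genes: Sequence[str]) -> "CohortTable":
        """Restrict to *genes*, keeping only patients with no missing value."""
        genes = list(genes)
        absent = [g for g in genes if g not in self.values.columns]
        if absent:
            raise CohortFormatError(f"genes not in cohort: {absent}")
        sub = self.values[genes]
        keep = sub.notna().all(axis=1)
        return CohortTable(sub.loc[keep], self.labels.loc[keep], self.source)

    def matrix(self, genes: Sequence[str] | None = None) -> np.ndarray:
        return self.values[list(genes) if genes else self.genes].to_numpy()

    # -- I/O --------------------------------------------------------------

    def save(self, path: str | Path, dialect: str = "csv") -> None:
        """Write ``patient_id,label,<gene>...``; missing cells are empty."""
        sep = {"csv": ",", "tsv": "\t"}[dialect]
        out = self.values.copy()
        out.insert(0, "label", self.labels)
        out.index.name = "patient_id"
        out.to_csv(path, sep=sep)


def load_cohort(path: str | Path, dialect: str = "csv") -> CohortTable:
    """Read a cohort table written by :meth:`CohortTable.save`.

    The header must be ``patient_id,label,<gene symbols>``; blank or ``NA``
    cells become missing values.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise CohortFormatError(f"unknown dialect: {dialect!r}")
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
    if "label" not in df.columns:
        raise CohortFormatError("cohort table has no 'label' column")
    labels = df.pop("label").astype(str)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise CohortFormatError(f"non-numeric expression value: {exc}") from exc
    return CohortTable(values, labels)
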