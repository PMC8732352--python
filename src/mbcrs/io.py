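"""Containers and file formats.

The pipeline exchanges three plain-text artifacts: a probe-by-sample beta
matrix (CSV/TSV, probe IDs in the first column), a per-sample QC metadata
table, and a per-woman phenotype table.  A reader for GEO series-matrix style
tables (tab-separated, ``ID_REF`` first column, ``!`` comment lines) is
provided for external validation runs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_qc",
    "write_sample_qc",
    "read_phenotypes",
    "write_phenotypes",
    "read_geo_series_matrix",
    "PHENOTYPE_REQUIRED_COLUMNS",
]

PHENOTYPE_REQUIRED_COLUMNS = (
    "sample_id", "age_entry", "age_exit", "event", "subtype", "er_status",
    "subcohort", "prs",
)


@dataclass
class MethylationMatrix:
    """Probe-by-sample methylation beta values plus per-sample QC metadata.

    ``beta`` is a DataFrame indexed by probe ID with one column per sample
    (values are methylation proportions in [0, 1]; NaN marks missing).
    ``sample_qc`` is indexed by sample ID with columns ``mean_intensity``
    (arbitrary fluorescence units) and ``low_quality_fraction`` (proportion
    of probes failing the probe-level quality rules).
    """

    beta: pd.DataFrame
    sample_qc: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.sample_qc is None:
            self.sample_qc = pd.DataFrame(
                {"mean_intensity": np.nan, "low_quality_fraction": np.nan},
                index=self.beta.columns,
            )
        self.validate()

    def validate(self):
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        missing = set(self.beta.columns) - set(self.sample_qc.index)
        if missing:
            raise ValueError(
                f"sample_qc metadata missing for samples: {sorted(missing)[:5]}..."
                if len(missing) > 5 else
                f"sample_qc metadata missing for samples: {sorted(missing)}"
            )
        if self.beta.index.duplicated().any():
            raise ValueError("duplicated probe IDs")
        if self.beta.columns.duplicated().any():
            raise ValueError("duplicated sample IDs")

    @property
    def probe_ids(self):
        return list(self.beta.index)

    @property
    def sample_ids(self):
        return list(self.beta.columns)

    @property
    def n_samples(self):
        return self.beta.shape[1]

    @property
    def n_probes(self):
        return self.beta.shape[0]

    def select_samples(self, sample_ids) -> "MethylationMatrix":
        sample_ids = list(sample_ids)
        return MethylationMatrix(
            beta=self.beta[sample_ids].copy(),
            sample_qc=self.sample_qc.loc[sample_ids].copy(),
        )


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def write_beta_matrix(matrix: MethylationMatrix, path) -> None:
    df = matrix.beta.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep=_sep_for(path), float_format="%.17g")


def read_beta_matrix(path, qc_path=None) -> MethylationMatrix:
    beta = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    beta.index = beta.index.astype(str)
    beta.columns = beta.columns.astype(str)
    qc = read_sample_qc(qc_path) if qc_path is not None else None
    return MethylationMatrix(beta=beta, sample_qc=qc)


def write_sample_qc(matrix: MethylationMatrix, path) -> None:
    df = matrix.sample_qc.copy()
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.17g")


def read_sample_qc(path) -> pd.DataFrame:
    qc = pd.read_csv(path, index_col=0)
    qc.index = qc.index.astype(str)
    return qc


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False, float_format="%.17g")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PHENOTYPE_REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table lacks required columns: {sorted(missing)}")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def read_geo_series_matrix(path) -> pd.DataFrame:
    """Read a GEO series-matrix style methylation table.

    Lines starting with ``!`` are metadata and skipped; the data block is
    tab-separated with probe IDs in an ``ID_REF`` first column.  Returns a
    probe-by-sample DataFrame (does not attach QC metadata).
    """
    df = pd.read_csv(path, sep="\t", comment="!")
    first = df.columns[0]
    if first.strip('"') != "ID_REF":
        raise ValueError(f"expected ID_REF first column, found {first!r}")
    df = df.set_index(first)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = [c.strip('"') for c in df.columns]
    return df.apply(pd.to_numeric, errors="coerce")
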