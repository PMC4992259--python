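"""Surrogate-gene expression handling: I/O, normalization, parameterization.

PR-B transcriptional activity is inferred from two PR-B-responsive surrogate
transcripts (FOXO1A, FKBP5) and inflammatory load from three pro-inflammatory
surrogates (IL1B, IL6, IL8).  Expression is min-max normalized per gene
within each platform cohort, ``N = (G - m)/(M - m)``, which nondimensionalizes
the data onto [0, 1] and makes the natural critical levels ``B_c = I_c = 1``.
A *predictor* is a pair (PR-B surrogate, inflammatory surrogate); for each
sample it assigns ``b`` and ``i`` directly from the normalized values, with
``k = 1`` by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .ode_model import DimensionlessParams, LaborBasinError

__all__ = [
    "PRB_GENES",
    "INFLAMMATORY_GENES",
    "SURROGATE_GENES",
    "GENE_ALIASES",
    "PLATFORMS",
    "GROUPS",
    "Cohort",
    "Predictor",
    "SchemaError",
    "DegenerateGeneError",
    "NormalizationStateError",
    "all_predictors",
    "read_cohort",
    "minmax_normalize",
    "parameterize",
    "parameter_table",
]

PRB_GENES = ("FOXO1A", "FKBP5")
INFLAMMATORY_GENES = ("IL1B", "IL6", "IL8")
SURROGATE_GENES = PRB_GENES + INFLAMMATORY_GENES

PLATFORMS = ("microarray", "rnaseq")
GROUPS = ("IL", "NIL")

# dataset naming conventions vary; resolved case-insensitively after
# stripping hyphens/Greek beta
GENE_ALIASES = {
    "FOXO1": "FOXO1A",
    "FOXO1A": "FOXO1A",
    "FKBP5": "FKBP5",
    "IL1B": "IL1B",
    "IL1": "IL1B",
    "IL1BETA": "IL1B",
    "IL6": "IL6",
    "IL8": "IL8",
    "CXCL8": "IL8",
}

_METADATA_COLUMNS = ("sample_id", "platform", "group")


class SchemaError(LaborBasinError):
    """The expression table violates the expected schema."""


class DegenerateGeneError(LaborBasinError):
    """A (platform, gene) stratum is constant: min-max normalization undefined."""


class NormalizationStateError(LaborBasinError):
    """Operation requires the other normalization state of the cohort."""


def _canonical_gene(name: str) -> str | None:
    key = (
        str(name)
        .strip()
        .upper()
        .replace("-", "")
        .replace("_", "")
        .replace("Β", "BETA")
        .replace("β".upper(), "BETA")
    )
    return GENE_ALIASES.get(key)


@dataclass(frozen=True)
class Predictor:
    """An ordered surrogate pair: one PR-B-responsive, one inflammatory gene."""

    prb_gene: str
    infl_gene: str

    def __post_init__(self):
        if self.prb_gene not in PRB_GENES:
            raise ValueError(f"prb_gene must be one of {PRB_GENES}, got {self.prb_gene!r}")
        if self.infl_gene not in INFLAMMATORY_GENES:
            raise ValueError(
                f"infl_gene must be one of {INFLAMMATORY_GENES}, got {self.infl_gene!r}"
            )

    @property
    def name(self) -> str:
        return f"{self.infl_gene}-{self.prb_gene}"


def all_predictors() -> list[Predictor]:
    """The six possible predictors (2 PR-B x 3 inflammatory surrogates)."""
    return [Predictor(p, g) for p, g in product(PRB_GENES, INFLAMMATORY_GENES)]


@dataclass(frozen=True)
class Cohort:
    """Surrogate-gene expression with platform/group metadata.

    ``data`` is a sample x column table holding the three metadata columns
    and exactly the five surrogate genes; ``normalized`` records whether
    within-platform min-max normalization has been applied.
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self):
        df = self.data
        missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing metadata column(s): {missing}")
        genes = [c for c in df.columns if c not in _METADATA_COLUMNS]
        if sorted(genes) != sorted(SURROGATE_GENES):
            raise SchemaError(
                f"gene columns must be exactly {sorted(SURROGATE_GENES)}, got {sorted(genes)}"
            )
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise SchemaError(f"duplicate sample_id(s): {dupes}")
        for col in ("platform", "group"):
            allowed = PLATFORMS if col == "platform" else GROUPS
            bad = df.loc[~df[col].isin(allowed)]
            if len(bad):
                row = bad.iloc[0]
                raise SchemaError(
                    f"unknown {col} {row[col]!r} for sample {row['sample_id']!r}; "
                    f"accepted tokens: {list(allowed)}"
                )
        for gene in SURROGATE_GENES:
            vals = pd.to_numeric(df[gene], errors="coerce")
            if vals.isna().any():
                sid = df.loc[vals.isna(), "sample_id"].iloc[0]
                raise SchemaError(f"missing or non-numeric value in column {gene!r} for sample {sid!r}")

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    @property
    def groups(self) -> pd.Series:
        return self.data.set_index("sample_id")["group"]

    def ids_in_group(self, group: str) -> list[str]:
        return sorted(self.data.loc[self.data["group"] == group, "sample_id"])

    def expression(self, gene: str) -> pd.Series:
        """Expression of one surrogate gene indexed by sample_id."""
        return self.data.set_index("sample_id")[gene]


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort expression table from CSV or TSV.

    The file must carry columns ``sample_id``, ``platform``, ``group`` and
    the five surrogate genes (aliases like FOXO1 or IL-1β are accepted and
    canonicalized).  Platform and group tokens are matched case-insensitively.
    Schema violations raise :class:`SchemaError` naming the offending cell.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep)

    renames = {}
    for col in df.columns:
        canon = _canonical_gene(col)
        if canon is not None and col != canon:
            renames[col] = canon
        elif str(col).strip().lower() in _METADATA_COLUMNS and col != str(col).strip().lower():
            renames[col] = str(col).strip().lower()
    df = df.rename(columns=renames)

    for col in _METADATA_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing metadata column(s): [{col!r}]")
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    df["platform"] = df["platform"].astype(str).str.strip().str.lower()
    df["group"] = df["group"].astype(str).str.strip().str.upper()
    platform_aliases = {"microarray": "microarray", "array": "microarray",
                        "rnaseq": "rnaseq", "rna-seq": "rnaseq", "rna_seq": "rnaseq"}
    df["platform"] = df["platform"].map(lambda p: platform_aliases.get(p, p))
    return Cohort(data=df.reset_index(drop=True), normalized=False)


def minmax_normalize(cohort: Cohort, pooled: bool = False) -> Cohort:
    """Min-max normalize each gene, by default within each platform cohort.

    Every gene column is mapped by ``(G - m)/(M - m)`` with ``m``/``M`` the
    stratum minimum/maximum, so each (platform, gene) stratum spans exactly
    [0, 1].  ``pooled=True`` instead takes min/max over all samples jointly.
    A constant stratum raises :class:`DegenerateGeneError`; a cohort that is
    already normalized is rejected rather than silently re-scaled.
    """
    if cohort.normalized:
        raise NormalizationStateError("cohort is already normalized")
    df = cohort.data.copy()
    strata = [("all", df.index)] if pooled else [
        (platform, df.index[df["platform"] == platform])
        for platform in df["platform"].unique()
    ]
    for platform, idx in strata:
        if len(idx) < 2:
            raise DegenerateGeneError(
                f"platform {platform!r} has fewer than 2 samples; normalization undefined"
            )
        for gene in SURROGATE_GENES:
            vals = df.loc[idx, gene].astype(float)
            m, M = vals.min(), vals.max()
            if M == m:
                raise DegenerateGeneError(
                    f"gene {gene!r} is constant ({m}) within platform {platform!r}"
                )
            df.loc[idx, gene] = (vals - m) / (M - m)
    return Cohort(data=df, normalized=True)


def parameterize(cohort: Cohort, predictor: Predictor) -> dict[str, DimensionlessParams]:
    """Per-sample model parameters under ``predictor``.

    For each sample, ``b`` is its normalized PR-B-surrogate value and ``i``
    its normalized inflammatory-surrogate value; ``k = 1`` by the prediction
    convention (with implied critical levels ``B_c = I_c = 1``).
    """
    if not cohort.normalized:
        raise NormalizationStateError("cohort must be normalized before parameterization")
    b_vals = cohort.expression(predictor.prb_gene)
    i_vals = cohort.expression(predictor.infl_gene)
    return {
        sid: DimensionlessParams(b=float(b_vals[sid]), i=float(i_vals[sid]), k=1.0)
        for sid in cohort.sample_ids
    }


def parameter_table(cohort: Cohort) -> pd.DataFrame:
    """Long-format parameter table over all six predictors.

    Columns: sample_id, predictor, b, i, k.
    """
    rows = []
    for predictor in all_predictors():
        for sid, params in parameterize(cohort, predictor).items():
            rows.append(
                {"sample_id": sid, "predictor": predictor.name,
                 "b": params.b, "i": params.i, "k": params.k}
            )
    return pd.DataFrame(rows)
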