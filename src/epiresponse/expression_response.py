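"""Per-gene log2 fold changes and up/down/unchanged response labels.

The direction of the transcriptional response to a drug dose is summarised
per gene as lfc = log2(TPM_treated + c) - log2(TPM_untreated + c) with a
pseudocount c (default 1) bounding the ratio for unexpressed genes.  The
response classes mirror the top-N ranking approach: the N most up- and
N most down-regulated genes form the two classes; everything else is
"unchanged".  No dispersion modelling or p-values: the method ranks by
direction and magnitude only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNTREATED = "untreated"


@dataclass(frozen=True)
class ExpressionTable:
    """Genes x conditions TPM matrix; one untreated column plus >= 1 doses."""

    frame: pd.DataFrame  # index gene_id, columns condition ids

    def __post_init__(self) -> None:
        df = self.frame
        if df.columns.duplicated().any():
            raise ValueError("condition ids must be unique")
        if df.index.duplicated().any():
            raise ValueError("gene ids must be unique")
        if (df.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.frame.columns)

    @classmethod
    def from_tsv(cls, path: str) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        return cls(df)

    def to_tsv(self, path: str) -> None:
        self.frame.to_csv(path, sep="\t", index_label="gene_id")


@dataclass(frozen=True)
class ResponseLabels:
    """Per-gene lfc and label in {up, down, unchanged} for one dose."""

    dose: str
    frame: pd.DataFrame = field(repr=False)  # index gene_id; columns lfc, label

    def __post_init__(self) -> None:
        if not {"lfc", "label"}.issubset(self.frame.columns):
            raise ValueError("labels frame needs 'lfc' and 'label' columns")
        bad = set(self.frame["label"]) - {"up", "down", "unchanged"}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    @property
    def up_genes(self) -> list[str]:
        return list(self.frame.index[self.frame["label"] == "up"])

    @property
    def down_genes(self) -> list[str]:
        return list(self.frame.index[self.frame["label"] == "down"])

    @classmethod
    def from_tsv(cls, path: str) -> "ResponseLabels":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        dose = str(df["dose"].iloc[0]) if "dose" in df.columns and len(df) else ""
        return cls(dose, df[["lfc", "label"]])

    def to_tsv(self, path: str) -> None:
        out = self.frame.copy()
        out["dose"] = self.dose
        out.to_csv(path, sep="\t", index_label="gene_id")


def log2_fold_change(
    table: ExpressionTable,
    dose: str,
    untreated: str = UNTREATED,
    pseudocount: float = 1.0,
) -> pd.Series:
    """lfc_g = log2(treated_g + pseudocount) - log2(untreated_g + pseudocount)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    for col in (dose, untreated):
        if col not in table.frame.columns:
            raise KeyError(f"condition column {col!r} not in expression table")
    t = table.frame[dose].to_numpy(dtype=np.float64)
    u = table.frame[untreated].to_numpy(dtype=np.float64)
    lfc = np.log2(t + pseudocount) - np.log2(u + pseudocount)
    return pd.Series(lfc, index=table.frame.index, name="lfc")


def select_response_genes(lfc: pd.Series, n: int = 1000, dose: str = "") -> ResponseLabels:
    """Label the top-n lfc genes "up", the bottom-n "down", the rest "unchanged".

    Ties at either boundary are broken by lexicographic gene id; the up set
    is taken first, then the down set from the remaining genes, so the two
    sets are always disjoint.
    """
    if len(lfc) < 2 * n:
        raise ValueError(
            f"need >= {2 * n} genes for n={n}; got {len(lfc)} (use a smaller n)"
        )
    if not np.all(np.isfinite(lfc.to_numpy())):
        raise ValueError("lfc must be finite for all genes")
    order_desc = lfc.rename("lfc").to_frame().assign(_gid=lfc.index).sort_values(
        ["lfc", "_gid"], ascending=[False, True], kind="mergesort"
    )
    up = list(order_desc.index[:n])
    rest = order_desc.index[n:]
    order_asc = lfc.loc[rest].rename("lfc").to_frame().assign(_gid=rest).sort_values(
        ["lfc", "_gid"], ascending=[True, True], kind="mergesort"
    )
    down = list(order_asc.index[:n])
    labels = pd.Series("unchanged", index=lfc.index, name="label")
    labels.loc[up] = "up"
    labels.loc[down] = "down"
    frame = pd.DataFrame({"lfc": lfc, "label": labels})
    return ResponseLabels(dose=dose, frame=frame)


def select_discordant(
    lfc_a: pd.Series,
    lfc_b: pd.Series,
    up_fold: float = 3.0,
    down_fold: float = 1.0 / 3.0,
) -> tuple[list[str], list[str]]:
    """Genes responding in opposite directions in two cohorts.

    ``set1``: fold change (2**lfc) strictly > ``up_fold`` in cohort A and
    strictly < ``down_fold`` in cohort B; ``set2`` is the reverse.  The gene
    universes are intersected by gene id first.
    """
    common = lfc_a.index.intersection(lfc_b.index)
    if len(common) == 0:
        raise ValueError("no genes shared between the two cohorts")
    fa = np.exp2(lfc_a.loc[common].to_numpy(dtype=np.float64))
    fb = np.exp2(lfc_b.loc[common].to_numpy(dtype=np.float64))
    set1 = sorted(common[(fa > up_fold) & (fb < down_fold)])
    set2 = sorted(common[(fb > up_fold) & (fa < down_fold)])
    return set1, set2
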