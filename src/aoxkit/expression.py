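"""Expression matrices for heat-map display: abundance and
treatment-vs-control log2 ratio matrices."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from aoxkit.core import AoxkitError


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame      # rows: isoforms, cols: conditions
    kind: str                 # "abundance" or "log2_ratio"

    def __post_init__(self) -> None:
        if self.kind not in ("abundance", "log2_ratio"):
            raise AoxkitError(f"unknown matrix kind {self.kind!r}")
        if self.kind == "abundance" and (self.values.to_numpy() < 0).any():
            raise AoxkitError("abundance matrix contains negative values")


def read_tpm_table(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, "abundance")


def ratio_matrix(
    abundance: ExpressionMatrix,
    pairs: list[tuple[str, str]],
    pseudocount: float = 0.01,
    log2: bool = True,
) -> ExpressionMatrix:
    """Treatment-vs-control ratios, one output column per (treatment, control)
    pair, log2 by default.  Row order and pair order are preserved."""
    if abundance.kind != "abundance":
        raise AoxkitError("ratio_matrix requires an abundance matrix")
    if pseudocount < 0:
        raise AoxkitError("pseudocount must be >= 0")
    df = abundance.values
    out = {}
    for treatment, control in pairs:
        for col in (treatment, control):
            if col not in df.columns:
                raise AoxkitError(f"unmatched column name {col!r}")
        ratio = (df[treatment] + pseudocount) / (df[control] + pseudocount)
        out[f"{treatment}/{control}"] = np.log2(ratio) if log2 else ratio
    result = pd.DataFrame(out, index=df.index)
    return ExpressionMatrix(result, "log2_ratio" if log2 else "abundance")


def export_heatmap_matrix(
    matrix: ExpressionMatrix, path: str | Path, image: str | Path | None = None
) -> Path:
    """Write the matrix as a bit-stable TSV; optionally render a heat map.

    The image is cosmetic (no pixel guarantees); the TSV preserves row and
    column order verbatim.
    """
    path = Path(path)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        matrix.values.to_csv(path, sep="\t", float_format="%.6g")
    except OSError as exc:
        raise AoxkitError(f"cannot write matrix to {path}: {exc}") from exc
    if image is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4, 0.4 * matrix.values.shape[1] + 2),
                     max(3, 0.25 * matrix.values.shape[0] + 1))
        )
        im = ax.imshow(matrix.values.to_numpy(), aspect="auto", cmap="RdBu_r")
        ax.set_xticks(range(matrix.values.shape[1]))
        ax.set_xticklabels(matrix.values.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(matrix.values.shape[0]))
        ax.set_yticklabels(matrix.values.index, fontsize=6)
        fig.colorbar(im, ax=ax, label=matrix.kind)
        fig.tight_layout()
        fig.savefig(image, dpi=150)
        plt.close(fig)
    return path
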