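"""Non-interactive figure rendering and tabular export.

Figures are secondary outputs: every figure writes its underlying numbers
as a CSV next to the PNG, so downstream checks never parse pixels.
Rendering is deterministic for fixed inputs (Agg backend, fixed color
limits when given).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .association import AssociationMap, neglog10_display
from .connectivity import SymmetricMap
from .exceptions import RequestError

__all__ = ["RenderSpec", "render"]

FIGURE_KINDS = (
    "fc_heatmap",
    "assoc_two_panel",
    "histogram_by_group",
    "component_map",
    "weight_map",
)


@dataclass
class RenderSpec:
    """What to draw and where to put it."""

    out_path: str | Path
    kind: str
    vmin: float | None = None
    vmax: float | None = None
    title: str = ""
    group_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in FIGURE_KINDS:
            raise RequestError(
                f"unknown figure kind {self.kind!r}; choose from {FIGURE_KINDS}"
            )
        self.out_path = Path(self.out_path)


def _heatmap(ax, matrix: np.ndarray, spec: RenderSpec, label: str = ""):
    lim = np.nanmax(np.abs(matrix)) if np.isfinite(matrix).any() else 1.0
    vmin = spec.vmin if spec.vmin is not None else -lim
    vmax = spec.vmax if spec.vmax is not None else lim
    im = ax.imshow(matrix, cmap="RdBu_r", vmin=vmin, vmax=vmax)
    ax.set_xlabel("region")
    ax.set_ylabel("region")
    if label:
        ax.set_title(label)
    return im


def _write_sidecar(spec: RenderSpec, frame: pd.DataFrame) -> None:
    frame.to_csv(Path(spec.out_path).with_suffix(".csv"), index=False)


def render(obj, spec: RenderSpec) -> Path:
    """Render a map, association, or grouped values to PNG (+ CSV sidecar).

    Accepted inputs by kind:

    * ``fc_heatmap`` / ``component_map`` / ``weight_map`` — a
      :class:`SymmetricMap` (or edge matrix already reshaped);
    * ``assoc_two_panel`` — an :class:`AssociationMap` over edges, drawn as
      the r map next to the clipped -log10 Bonferroni p map;
    * ``histogram_by_group`` — a mapping group label -> 1-D values.
    """
    out = Path(spec.out_path)
    out.parent.mkdir(parents=True, exist_ok=True)

    if spec.kind in ("fc_heatmap", "component_map", "weight_map"):
        if not isinstance(obj, SymmetricMap):
            raise RequestError(f"{spec.kind} expects a SymmetricMap")
        fig, ax = plt.subplots(figsize=(5, 4))
        im = _heatmap(ax, obj.matrix, spec, label=spec.title or spec.kind)
        fig.colorbar(im, ax=ax)
        vec = obj.to_vector()
        _write_sidecar(spec, pd.DataFrame({"edge": np.arange(len(vec)), "value": vec}))
    elif spec.kind == "assoc_two_panel":
        if not isinstance(obj, AssociationMap):
            raise RequestError("assoc_two_panel expects an AssociationMap")
        m = len(obj)
        p = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
        r_map = SymmetricMap.from_vector(obj.r, p, scale="r")
        disp = neglog10_display(obj)
        d_map = SymmetricMap.from_vector(disp, p, scale="neglog10_p_adj")
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        im0 = _heatmap(axes[0], r_map.matrix, RenderSpec(out, spec.kind, -1, 1), "r")
        fig.colorbar(im0, ax=axes[0])
        im1 = axes[1].imshow(d_map.matrix, cmap="viridis", vmin=0, vmax=5)
        axes[1].set_title("-log10 Bonferroni p (clipped at 5)")
        fig.colorbar(im1, ax=axes[1])
        if spec.title:
            fig.suptitle(spec.title)
        _write_sidecar(spec, obj.to_frame())
    elif spec.kind == "histogram_by_group":
        if not isinstance(obj, dict):
            raise RequestError(
                "histogram_by_group expects {group label: values} mapping"
            )
        fig, ax = plt.subplots(figsize=(5, 4))
        rows = []
        for label, values in obj.items():
            values = np.asarray(values, dtype=float)
            values = values[np.isfinite(values)]
            ax.hist(values, bins=20, alpha=0.5, label=str(label), density=True)
            rows.append(
                {
                    "group": str(label),
                    "n": len(values),
                    "mean": float(values.mean()) if len(values) else np.nan,
                    "sd": float(values.std(ddof=1)) if len(values) > 1 else np.nan,
                }
            )
        ax.legend()
        if spec.title:
            ax.set_title(spec.title)
        _write_sidecar(spec, pd.DataFrame(rows))
    else:  # pragma: no cover - RenderSpec already validates
        raise RequestError(f"unknown figure kind {spec.kind!r}")

    fig.savefig(out, dpi=100)
    plt.close(fig)
    return out
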