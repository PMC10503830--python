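"""Per-subject HTML reports: slice mosaics of computed maps per visit,
the AIF curve when available, and the response tables."""

from __future__ import annotations

import base64
import io as _io
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>qmripd report — {subject}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
h2 {{ border-bottom: 1px solid #999; }}
table {{ border-collapse: collapse; }}
td, th {{ border: 1px solid #bbb; padding: 4px 8px; }}
img {{ image-rendering: pixelated; }}
</style></head><body>
<h1>Quantitative-MRI response report — subject {subject}</h1>
{sections}
</body></html>
"""


def _fig_to_b64(fig) -> str:
    buf = _io.BytesIO()
    fig.savefig(buf, format="png", dpi=80, bbox_inches="tight")
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode()


def _mosaic(pmap, title: str) -> str:
    vals = np.where(pmap.valid, pmap.values, np.nan)
    n_slices = vals.shape[2]
    cols = min(n_slices, 8)
    rows = int(np.ceil(n_slices / cols))
    fig, axes = plt.subplots(rows, cols, figsize=(2 * cols, 2 * rows), squeeze=False)
    for i in range(rows * cols):
        ax = axes[i // cols][i % cols]
        ax.axis("off")
        if i < n_slices:
            ax.imshow(vals[:, :, i].T, origin="lower", cmap="viridis")
    fig.suptitle(title)
    return f'<img src="data:image/png;base64,{_fig_to_b64(fig)}" alt="{title}">'


def _aif_plot(aif) -> str:
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(aif.times, aif.cp, "-o", ms=3)
    if aif.arrival_frame is not None:
        ax.axvline(aif.times[aif.arrival_frame], ls="--", c="r", label="arrival")
        ax.legend()
    ax.set_xlabel("time (s)")
    ax.set_ylabel("plasma Gd (mM)")
    return f'<img src="data:image/png;base64,{_fig_to_b64(fig)}" alt="AIF">'


def _df_to_html(df) -> str:
    return df.to_html(index=False, float_format=lambda v: f"{v:.4g}")


def render_report(result, subject: str, out_path: str | Path,
                  aif=None) -> Path:
    """Write one subject's HTML report from a pipeline result."""
    sections = []
    visits = result.maps.get(subject, {})
    for visit in visits:
        parts = [f"<h2>Visit: {visit}</h2>"]
        for name, pmap in sorted(visits[visit].items()):
            parts.append(_mosaic(pmap, f"{name} ({pmap.units})" if pmap.units
                                 else name))
        sections.append("\n".join(parts))
    if aif is not None:
        sections.append("<h2>Arterial input function</h2>" + _aif_plot(aif))
    if len(result.measurements):
        sub = result.measurements[result.measurements.subject_id == subject]
        if len(sub):
            sections.append("<h2>VOI medians</h2>" + _df_to_html(sub))
    if len(result.labels):
        sub = result.labels[result.labels.subject_id == subject]
        if len(sub):
            sections.append("<h2>Pharmacodynamic response labels</h2>"
                            + _df_to_html(sub))
    html = _PAGE.format(subject=subject, sections="\n".join(sections))
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(html)
    return out_path
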