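"""Human-readable diagnostics for a completed backward-selection run.

``render_trace`` produces the variables-by-iterations relevance grid (cells
blank after a variable's removal) with the rejection counts ``R_l(alpha)``
as the final row.  ``iteration_histograms`` bins each iteration's p-value
vectors into 20 right-closed bins on [0, 1] for p-value histogram
diagnostics; when plotted, each histogram's vertical axis should be scaled
to its own tallest bar so shape differences stay visible.

Both are pure functions of the persisted trace — no model refits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .backward_selection import SelectionTrace

__all__ = ["render_trace", "iteration_histograms"]

N_BINS = 20


def _var_label(trace: SelectionTrace, j: int) -> str:
    if trace.var_names and j - 1 < len(trace.var_names):
        return trace.var_names[j - 1]
    return f"var{j}"


def render_trace(trace: SelectionTrace, format: str = "tsv") -> str:
    """Relevance-by-iteration grid plus the R_l(alpha) row ('tsv' or 'markdown')."""
    k = len(trace.iterations[0].S)
    cols = [f"l={rec.ell}" for rec in trace.iterations]
    variables = list(trace.iterations[0].S)
    grid = pd.DataFrame("", index=[_var_label(trace, j) for j in variables],
                        columns=cols, dtype=object)
    for rec in trace.iterations:
        for j in rec.S:
            val = rec.relevance[j]
            cell = f"{int(val)}" if trace.measure == "p05" else f"{val:.4f}"
            grid.loc[_var_label(trace, j), f"l={rec.ell}"] = cell
    rrow = {f"l={rec.ell}": str(rec.R) for rec in trace.iterations}
    grid.loc[f"R_l({trace.alpha:g})"] = pd.Series(rrow).reindex(cols).fillna("")
    if format == "tsv":
        return grid.to_csv(sep="\t", index_label="variable")
    if format == "markdown":
        header = "| variable | " + " | ".join(cols) + " |"
        rule = "|" + "---|" * (len(cols) + 1)
        lines = [header, rule]
        for name, row in grid.iterrows():
            lines.append("| " + name + " | " + " | ".join(row.astype(str)) + " |")
        note = (f"\nSelected iteration l*={trace.ell_star} "
                f"(measure={trace.measure}); removed order: "
                + " > ".join(_var_label(trace, rec.removed)
                             for rec in trace.iterations if rec.removed) + ".")
        return "\n".join(lines) + note + "\n"
    raise ValueError(f"unknown format {format!r}")


def iteration_histograms(trace: SelectionTrace) -> pd.DataFrame:
    """20-bin p-value histogram counts per (iteration, variable).

    Bins are right-closed (p = 0 falls in bin 1), matching the q-value
    machinery's convention; counts sum to the number of non-NaN p-values.
    """
    rows = []
    for rec in trace.iterations:
        for j in rec.S:
            p = rec.pvalues[j]
            p = p[~np.isnan(p)]
            bins = np.clip(np.ceil(p * N_BINS).astype(int), 1, N_BINS)
            counts = np.bincount(bins, minlength=N_BINS + 1)[1:]
            row = {"ell": rec.ell, "variable": _var_label(trace, j),
                   "removed": rec.removed == j, "R": rec.R}
            row.update({f"bin{b + 1}": int(c) for b, c in enumerate(counts)})
            rows.append(row)
    return pd.DataFrame(rows)
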