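"""Optional heatmap figures (requires matplotlib).

Two views mirror the standard EWS reporting layout: a per-transition
significance matrix with Kendall's tau as color strength, and a
states x (indicator, transition type) grid of predictive values masked
where the EWS does not beat the transition prevalence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def ews_strength_heatmap(results, ax=None):
    """Transitions x states matrix of significant EWS, colored by tau."""
    import matplotlib.pyplot as plt

    rows = [
        r
        for r in results
        if r.segment_kind == "pre_transition" and r.valid
    ]
    if not rows:
        raise ValueError("no pre-transition results to plot")
    states = sorted({r.state for r in rows})
    segs = sorted({(r.patient_id, r.segment_id) for r in rows})
    mat = np.full((len(segs), len(states)), np.nan)
    for r in rows:
        if r.significant:
            i = segs.index((r.patient_id, r.segment_id))
            j = states.index(r.state)
            mat[i, j] = max(np.nan_to_num(mat[i, j]), r.tau)
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 0.4 * len(segs) + 2))
    im = ax.imshow(mat, aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(len(states)), states, rotation=90)
    ax.set_yticks(range(len(segs)), [s[1] for s in segs])
    ax.figure.colorbar(im, ax=ax, label="Kendall's tau")
    ax.set_xlabel("momentary state")
    return ax


def predictive_value_heatmap(table: pd.DataFrame, value: str = "ppv", ax=None):
    """States x (indicator, type) predictive values, prevalence-masked."""
    import matplotlib.pyplot as plt

    sub = table[table.state != "__any_state__"].copy()
    cols = [
        (ind, kind)
        for ind in sorted(sub.indicator.unique())
        for kind in sorted(sub.transition_kind.unique())
    ]
    states = sorted(sub.state.unique())
    mat = np.full((len(states), len(cols)), np.nan)
    for _, row in sub.iterrows():
        i = states.index(row.state)
        j = cols.index((row.indicator, row.transition_kind))
        if row.beats_prevalence:  # white tiles: no improvement over prevalence
            mat[i, j] = row[value]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.35 * len(states) + 2))
    im = ax.imshow(mat, aspect="auto", cmap="magma", vmin=0, vmax=1)
    ax.set_xticks(range(len(cols)), [f"{i}\n{k}" for i, k in cols])
    ax.set_yticks(range(len(states)), states)
    ax.figure.colorbar(im, ax=ax, label=value.upper())
    return ax
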