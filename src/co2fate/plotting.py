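"""Optional scatter exports: mixing-trajectory and clumped-isotopologue plots."""

from __future__ import annotations

import numpy as np

from .fractionation import hybrid_residual_delta
from .samples import ABSOLUTE_ZERO_C
from .thermometry import _eval_curve


def plot_mixing(results, ax=None, f_grid=None):
    """delta13C-CO2 against CO2/3He with model trajectories.

    Dashed lines are the pure-dissolution (F_d = 1) and pure-methanogenesis
    (F_d = 0) trajectories from the reference sample; the solid line is the
    hybrid curve at the fitted mean F_d.  Sample points are drawn for every
    fitted sample.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    model = results.model
    cfg = model.config
    s = results.field_summary
    ref = next(x for x in model.samples if x.sample_id == s.reference_id)
    f = np.linspace(0.05, 1.0, 200) if f_grid is None else np.asarray(f_grid)

    for f_d, style, label in (
        (1.0, "--", "dissolution only"),
        (0.0, ":", "methanogenesis only"),
        (s.mean_f_d, "-", f"hybrid (F_d = {s.mean_f_d:.2f})"),
    ):
        if not np.isfinite(f_d):
            continue
        deltas = [hybrid_residual_delta(s.delta_i, fi, f_d, cfg.factors, cfg.hybrid_mode) for fi in f]
        ax.plot(ref.co2_he3 * f, deltas, style, label=label)

    fitted_ids = {r.sample_id for r in results.results} | {s.reference_id}
    pts = [x for x in model.samples if x.sample_id in fitted_ids]
    ax.scatter([x.co2_he3 for x in pts], [x.d13c_co2 for x in pts], zorder=3, label="samples")
    ax.set_xlabel(r"CO$_2$/$^3$He")
    ax.set_ylabel(r"$\delta^{13}$C-CO$_2$ (permil VPDB)")
    ax.legend(fontsize=8)
    return ax


def plot_clumped(samples, calibrations, ax=None, t_range_k=(280.0, 650.0)):
    """Equilibrium locus in (cap-delta 13CH3D, cap-delta 12CH2D2) space with samples."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = np.linspace(*t_range_k, 300)
    d13 = _eval_curve(calibrations.d13ch3d_coeffs, t)
    d12 = _eval_curve(calibrations.d12ch2d2_coeffs, t)
    ax.plot(d13, d12, "k-", label="thermodynamic equilibrium")
    for tc in (50.0, 100.0, 200.0):
        tk = tc - ABSOLUTE_ZERO_C
        ax.annotate(
            f"{tc:.0f} C",
            (float(_eval_curve(calibrations.d13ch3d_coeffs, tk)),
             float(_eval_curve(calibrations.d12ch2d2_coeffs, tk))),
            fontsize=7,
        )
    pts = [s for s in samples if s.has_clumped()]
    if pts:
        ax.errorbar(
            [s.d13ch3d for s in pts],
            [s.d12ch2d2 for s in pts],
            xerr=[s.d13ch3d_sigma or 0.0 for s in pts],
            yerr=[s.d12ch2d2_sigma or 0.0 for s in pts],
            fmt="o",
            label="samples",
        )
    ax.set_xlabel(r"$\Delta^{13}$CH$_3$D (permil)")
    ax.set_ylabel(r"$\Delta^{12}$CH$_2$D$_2$ (permil)")
    ax.legend(fontsize=8)
    return ax
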