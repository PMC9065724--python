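"""Summarize the transient (entry-segment) characterization.

Fits the gamma distribution to the positive expansion-accelerations and
prints the constant-rdot goodness summaries (regression R^2, flight-distance
discrepancy, model-acceleration/set-point-error correlation) that support
treating entries as constant expansion-acceleration motion.
"""

import json
from pathlib import Path

import click
import numpy as np
import pandas as pd

from beeland.stats import fit_gamma, gamma_median_approx


@click.command()
@click.option("--entries", default="results/entries.csv", show_default=True)
@click.option("--out-dir", default="results", show_default=True, type=click.Path())
def main(entries, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tab = pd.read_csv(entries)
    pos = tab[(tab.delta_re_per_s > 0) & (tab.rdot_per_s2 > 0)]

    click.echo(f"{len(pos)} of {len(tab)} entries have a positive step "
               f"(like real landings, set-points mostly step upward)")
    g = fit_gamma(pos.rdot_per_s2.to_numpy())
    click.echo(f"expansion-acceleration: median {g.sample_median:.2f} 1/s^2; "
               f"gamma fit a = {g.a:.2f} [{g.ci_a[0]:.2f}, {g.ci_a[1]:.2f}], "
               f"b = {g.b:.2f} [{g.ci_b[0]:.2f}, {g.ci_b[1]:.2f}]")
    click.echo(f"gamma-implied median {gamma_median_approx(g.a, g.b):.2f} 1/s^2")
    click.echo(f"constant-rdot fit quality: R^2 median {tab.R2.median():.3f}, "
               f"delta_d median {tab.delta_d_m.median()*1000:.2f} mm, "
               f"corr(A_e, set-point error) median {tab.corr_Ae_dr.median():.3f}")
    ae_pos = (pos.Ae_mean_ms2 > 0).mean()
    click.echo(f"{100*ae_pos:.1f}% of positive-step entries have net "
               f"acceleration toward the surface")

    (out / "gamma_fit.json").write_text(json.dumps({
        "a": g.a, "ci_a": g.ci_a, "b": g.b, "ci_b": g.ci_b,
        "sample_median": g.sample_median, "n": g.n,
        "r2_median": float(tab.R2.median()),
        "delta_d_mm_median": float(tab.delta_d_m.median() * 1000),
        "corr_median": float(tab.corr_Ae_dr.median()),
    }, indent=2))


if __name__ == "__main__":
    main()
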