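"""Fit-band report: best-RMSE trajectory and 95 %-RMSE envelope per site.

Reads the posterior written by 03_local_calibration.py and writes one
plot-ready CSV per site (time, best trajectory, envelope bounds, best
plant-fraction trajectory) plus a per-site RMSE summary table.
"""

import logging
from pathlib import Path

import pandas as pd

from qsoc.cli import _chains_from_frame
from qsoc.io import load_site_datasets
from qsoc.projection import report_fit

logging.disable(logging.WARNING)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    datasets = load_site_datasets(
        ROOT / "data" / "sites.csv",
        ROOT / "data" / "observations.csv",
        ROOT / "data" / "climate.csv",
    )
    chains = _chains_from_frame(pd.read_csv(ROOT / "posterior.csv"))
    outdir = ROOT / "fits"
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ds in datasets:
        rep = report_fit(chains, ds)
        rep.to_frame().to_csv(outdir / f"fit_{ds.site_id}.csv", index=False)
        rows.append(
            {
                "site_id": ds.site_id,
                "rmse_best": rep.rmse_best,
                "rmse_mode": rep.rmse_mode,
                "rmse_mean": rep.rmse_mean,
                "rmse_percent_final": rep.rmse_percent_final,
            }
        )
        print(
            f"{ds.site_id}: best RMSE {rep.rmse_best:.2f}, mode {rep.rmse_mode:.2f}, "
            f"mean {rep.rmse_mean:.2f} Mg C/ha ({rep.rmse_percent_final:.1f} % of "
            "final stock)"
        )
    pd.DataFrame(rows).to_csv(ROOT / "fit_summary.csv", index=False)


if __name__ == "__main__":
    main()
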