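#!/usr/bin/env python
"""Render a monitoring plot from an examination_log.csv: per-epoch
validity with the control margins, plus stop/select markers.

Usage: python scripts/plot_examination.py run/examination_log.csv out.png
"""

import csv
import sys


def main() -> int:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    log_path, out_path = sys.argv[1], sys.argv[2]
    with open(log_path) as fh:
        rows = list(csv.DictReader(fh))
    epochs = [int(r["epoch"]) for r in rows]
    validity = [float(r["validity_percent"]) for r in rows]
    lower = float(rows[0]["lower_margin"])
    upper = float(rows[0]["upper_margin"])

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(epochs, validity, marker="o", label="validity %")
    ax.axhline(lower, ls="--", color="tab:red", label="lower margin")
    ax.axhline(upper, ls="--", color="tab:green", label="upper margin")
    for r in rows:
        if r["selected"] == "1":
            ax.axvline(
                int(r["epoch"]), color="tab:orange", alpha=0.6,
                label="selected epoch",
            )
        if r["stopped"] == "1":
            ax.axvline(
                int(r["epoch"]), color="tab:purple", alpha=0.6,
                label="stopped epoch",
            )
    ax.set_xlabel("epoch")
    ax.set_ylabel("valid SMILES (%)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    print(f"wrote {out_path}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
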