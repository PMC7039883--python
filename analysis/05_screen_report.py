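"""Plate QC, normalization and hit calling for both plates.

Validation plate: Z' from DMSO vs positive-control wells, the positive
control's percent of DMSO, and the lithium-like dose response with
unpaired-t-test stars. Screen plate: percent-of-DMSO normalization,
banded hit calls with the toxicity counter-screen, and recovery against
the planted labels. Also renders a screen heatmap under scratch/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gsk3screen.imaging.wells import WellResult
from gsk3screen.screen import (
    PlateLayout,
    call_hits,
    normalize_to_reference,
    unpaired_ttest,
    zprime,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
OUT = ROOT / "results"


def load_wells(tag: str) -> list[WellResult]:
    df = pd.read_csv(OUT / f"wells_{tag}.csv")
    return [
        WellResult(
            well=row["well"], n_fields=int(row["n_fields"]),
            neuron_count=int(row["neuron_count"]),
            percent_pcrmp2=(
                None if pd.isna(row["percent_pcrmp2"])
                else float(row["percent_pcrmp2"])
            ),
        )
        for _, row in df.iterrows()
    ]


def validation_report() -> None:
    layout = PlateLayout.from_csv(SCRATCH / "validation_plate" / "layout.csv")
    normalized = normalize_to_reference(load_wells("validation"), layout,
                                        mode="dmso")
    by_group: dict[str, list[float]] = {}
    for nw in normalized:
        compound, dose, _role = layout.wells[nw.well]
        by_group.setdefault(f"{compound}@{dose}", []).append(
            nw.normalized_percent
        )
    z = zprime(by_group["GSK3i@10.0"], by_group["DMSO@0.0"])
    print(f"validation plate Z' = {z.value:.2f} "
          f"(positive control at {np.mean(by_group['GSK3i@10.0']):.1f}% of DMSO)")
    rows = []
    for label, values in sorted(by_group.items()):
        test = unpaired_ttest(values, by_group["DMSO@0.0"]) \
            if label != "DMSO@0.0" else None
        rows.append(
            {
                "group": label,
                "mean_percent": float(np.mean(values)),
                "sd_percent": float(np.std(values, ddof=1)),
                "n": len(values),
                "p_vs_dmso": test.p if test else np.nan,
                "stars": test.stars if test else "",
            }
        )
        if label.startswith("lithium"):
            print(
                f"  {label}: {np.mean(values):.1f}% of DMSO "
                f"{rows[-1]['stars']}"
            )
    pd.DataFrame(rows).to_csv(OUT / "validation_report.tsv", sep="\t",
                              index=False)


def screen_report() -> None:
    layout = PlateLayout.from_csv(SCRATCH / "screen_plate" / "layout.csv")
    wells = load_wells("screen")
    normalized = normalize_to_reference(wells, layout, mode="dmso")
    by_compound: dict[str, list[float]] = {}
    counts: dict[str, list[int]] = {}
    for nw in normalized:
        if layout.role(nw.well) != "test":
            continue
        compound = layout.compound(nw.well)
        by_compound.setdefault(compound, []).append(nw.normalized_percent)
        counts.setdefault(compound, []).append(nw.neuron_count)
    by_well = {w.well: w for w in wells}
    ref = float(np.mean([
        by_well[w].neuron_count for w in layout.wells_with_role("DMSO")
    ]))
    ratios = {c: float(np.mean(v)) / ref for c, v in counts.items()}
    calls = call_hits(by_compound, ratios)
    frame = pd.DataFrame(
        [
            {
                "compound": h.compound, "mean_percent": h.mean_percent,
                "neuron_count_ratio": h.neuron_count_ratio, "band": h.band,
                "planted": h.compound.split("_")[0],
            }
            for h in calls
        ]
    )
    frame.to_csv(OUT / "screen_hits.tsv", sep="\t", index=False)
    recovered = (frame["band"] == frame["planted"]).mean()
    by_band = frame["band"].value_counts().to_dict()
    print(
        f"screen: {by_band} — {100 * recovered:.1f}% of planted labels "
        f"recovered"
    )
    heatmap(normalized, layout)


def heatmap(normalized, layout) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = np.full((8, 12), np.nan)
    for nw in normalized:
        row = ord(nw.well[0]) - ord("A")
        col = int(nw.well[1:]) - 1
        if nw.normalized_percent is not None:
            grid[row, col] = nw.normalized_percent
    fig, ax = plt.subplots(figsize=(7, 4))
    im = ax.imshow(grid, cmap="RdBu", vmin=40, vmax=160)
    ax.set_xticks(range(12), [str(c + 1) for c in range(12)])
    ax.set_yticks(range(8), list("ABCDEFGH"))
    fig.colorbar(im, label="% p-CRMP2/MAP2 of DMSO")
    fig.tight_layout()
    figdir = SCRATCH / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    fig.savefig(figdir / "screen_heatmap.png", dpi=150)
    plt.close(fig)
    print(f"heatmap written to {figdir / 'screen_heatmap.png'}")


def main() -> None:
    validation_report()
    screen_report()


if __name__ == "__main__":
    main()
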