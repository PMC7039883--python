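"""Run the high-content image analysis on both simulated plates.

Segments nuclei, applies the four-criterion collar-ring classifier,
traces neurites from MAP2 and writes per-cell and per-well tables
(MAP2-positive neuron counts and percent p-CRMP2/MAP2) under results/.
"""

from pathlib import Path

import pandas as pd
import tifffile

from gsk3screen.imaging.wells import (
    HCIConfig,
    analyze_field,
    cells_frame,
    measure_well,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
OUT = ROOT / "results"


def analyze_plate_dir(plate_dir: Path, tag: str) -> None:
    config = HCIConfig()
    fields_by_well: dict[str, list] = {}
    for path in sorted(plate_dir.glob("*.tif")):
        well = path.stem.rsplit("_f", 1)[0]
        fields_by_well.setdefault(well, []).append(
            analyze_field(tifffile.imread(path), config)
        )
    cells = []
    rows = []
    for well, fields in sorted(fields_by_well.items()):
        result = measure_well(well, fields)
        cells.append(cells_frame(well, fields))
        rows.append(
            {
                "well": well,
                "n_fields": result.n_fields,
                "neuron_count": result.neuron_count,
                "percent_pcrmp2": result.percent_pcrmp2,
            }
        )
    pd.concat(cells, ignore_index=True).to_csv(
        OUT / f"cells_{tag}.csv", index=False
    )
    wells = pd.DataFrame(rows)
    wells.to_csv(OUT / f"wells_{tag}.csv", index=False)
    print(
        f"{tag}: {len(wells)} wells, median {wells['neuron_count'].median():.0f} "
        f"MAP2+ neurons/well, percent range "
        f"{wells['percent_pcrmp2'].min():.1f}-{wells['percent_pcrmp2'].max():.1f}"
    )


def main() -> None:
    OUT.mkdir(exist_ok=True)
    analyze_plate_dir(SCRATCH / "validation_plate", "validation")
    analyze_plate_dir(SCRATCH / "screen_plate", "screen")


if __name__ == "__main__":
    main()
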