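"""Simulate the imaging plates: assay validation and the 96-well screen.

Writes two plates of three-channel TIFF fields under scratch/ (they are
bulky intermediates): a validation plate with DMSO and strong positive
control wells plus lithium-like doses, and a full 96-well screen with
planted strong / candidate / inactive / toxic compounds.
"""

from pathlib import Path

from gsk3screen.synth.plate_sim import (
    SyntheticPlateSpec,
    WellSpec,
    generate_plate,
    make_screen_layout,
    write_plate,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
SEED = 20260930


def validation_wells() -> dict[str, WellSpec]:
    wells = {}
    for i in range(1, 9):
        wells[f"A{i:02d}"] = WellSpec("DMSO", 0.0, "DMSO")
        wells[f"B{i:02d}"] = WellSpec(
            "GSK3i", 10.0, "positive_control", suppression=0.232
        )
    for i in range(1, 5):
        wells[f"C{i:02d}"] = WellSpec("lithium", 1.0, "test")
        wells[f"D{i:02d}"] = WellSpec("lithium", 2.5, "test")
    return wells


def main() -> None:
    validation = SyntheticPlateSpec(wells=validation_wells(), seed=SEED)
    write_plate(generate_plate(validation), SCRATCH / "validation_plate")
    print(
        f"validation plate: {len(validation.wells)} wells x "
        f"{validation.fields_per_well} fields -> "
        f"{SCRATCH / 'validation_plate'}"
    )

    screen = SyntheticPlateSpec(wells=make_screen_layout(), seed=SEED + 1)
    write_plate(generate_plate(screen), SCRATCH / "screen_plate")
    print(
        f"screen plate: {len(screen.wells)} wells x "
        f"{screen.fields_per_well} fields -> {SCRATCH / 'screen_plate'}"
    )


if __name__ == "__main__":
    main()
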