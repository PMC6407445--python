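"""Integer label conventions for the voxelised tissue model.

Tissue labels are small positive integers; implanted hardware uses a
separate range so that rasterisation can never collide with tissue codes.
"""

FAT = 1
BONE = 2
COLON = 3

INSULATOR = 100   # electrode shaft (and IPG case when inactive)
IPG = 101
CONTACT0 = 110    # contacts are CONTACT0 + k, k in 0..3

TISSUE_NAMES = {FAT: "fat", BONE: "bone", COLON: "colon"}

#: conductivities (S/m) tabulated at the stimulation frequency (14 Hz)
DEFAULT_CONDUCTIVITY = {FAT: 0.01, BONE: 0.02, COLON: 0.01}


def contact_label(k: int) -> int:
    if not 0 <= k <= 3:
        raise ValueError(f"contact index must be 0..3, got {k}")
    return CONTACT0 + k


def is_hardware(label: int) -> bool:
    return label >= INSULATOR


def is_contact(label: int) -> bool:
    return CONTACT0 <= label <= CONTACT0 + 3
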