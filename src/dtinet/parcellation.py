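"""AAL-90 style parcellation bookkeeping.

Region labels follow the standard automated-anatomical-labelling convention
for 90 cortical and subcortical regions: labels come in homotopic pairs
(2k-1, 2k) with odd = left hemisphere, even = right.
"""

from __future__ import annotations

__all__ = ["AAL90_ABBREVIATIONS", "aal90_region_names", "homotopic_pairs"]

# One abbreviation per homotopic pair, in the conventional AAL ordering.
AAL90_ABBREVIATIONS = [
    "PreCG", "SFGdor", "ORBsup", "MFG", "ORBmid", "IFGoperc", "IFGtriang",
    "ORBinf", "ROL", "SMA", "OLF", "SFGmed", "ORBsupmed", "REC", "INS",
    "ACG", "DCG", "PCG", "HIP", "PHG", "AMYG", "CAL", "CUN", "LING",
    "SOG", "MOG", "IOG", "FFG", "PoCG", "SPG", "IPL", "SMG", "ANG",
    "PCUN", "PCL", "CAU", "PUT", "PAL", "THA", "HES", "STG", "TPOsup",
    "MTG", "TPOmid", "ITG",
]


def aal90_region_names() -> dict[int, str]:
    """Label id -> abbreviation (suffix .L / .R) for the 90-region scheme."""
    names = {}
    for k, abbr in enumerate(AAL90_ABBREVIATIONS):
        names[2 * k + 1] = f"{abbr}.L"
        names[2 * k + 2] = f"{abbr}.R"
    return names


def homotopic_pairs(n_regions: int) -> list[tuple[int, int]]:
    """Homotopic (left, right) label pairs for an even region count."""
    if n_regions % 2 != 0:
        raise ValueError(f"region count must be even, got {n_regions}")
    return [(2 * k + 1, 2 * k + 2) for k in range(n_regions // 2)]
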