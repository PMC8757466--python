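"""The multiclass scheme: 21 polymer classes plus a catch-all matrix class.

Class identifiers follow the common abbreviations used in microplastics
spectroscopy. ``Other`` collects everything on the filter that is not one
of the target polymers (bio-organic residue, minerals, substrate vicinity)
and is treated as a regular class throughout.

The integer encoding of a class is its position in :data:`CLASS_IDS`;
``SUBSTRATE`` (-1) marks background pixels and is never a class.
"""

from __future__ import annotations

CLASS_IDS: tuple[str, ...] = (
    "PP",        # polypropylene
    "PE",        # polyethylene
    "PVC",       # polyvinyl chloride
    "PU",        # polyurethane
    "PET",       # polyethylene terephthalate
    "PS",        # polystyrene
    "ABS",       # acrylonitrile butadiene styrene
    "PA",        # polyamide
    "PC",        # polycarbonate
    "PMMA",      # poly(methyl methacrylate)
    "CA",        # cellulose acetate
    "EVAc",      # ethylene vinyl acetate
    "EVOH",      # ethylene vinyl alcohol
    "PAN",       # polyacrylonitrile
    "PBT",       # polybutylene terephthalate
    "PEEK",      # polyether ether ketone
    "POM",       # polyoxymethylene
    "PPSU",      # polyphenylsulfone
    "PSU",       # polysulfone
    "silicone",
    "PLA",       # polylactic acid
    "Other",     # matrix / non-polymer catch-all
)

N_CLASSES: int = len(CLASS_IDS)

#: Background marker in label maps; not a class.
SUBSTRATE: int = -1

_INDEX = {name: i for i, name in enumerate(CLASS_IDS)}


def class_index(class_id: str) -> int:
    """Return the integer code of a class id; raises KeyError for unknown ids."""
    return _INDEX[class_id]


def class_name(index: int) -> str:
    """Inverse of :func:`class_index`."""
    return CLASS_IDS[index]
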