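"""Anatomical measurement regions for impinging osteophytes.

Five sites are measured: three in the simulated full-extension (0deg)
position -- the medial olecranon (posteromedial humeroulnar joint), the
lateral olecranon (posterolateral humeroulnar joint) and the posterior
capitellum -- and two in the simulated full-flexion (140deg) position --
the coronoid process (anterior humeroulnar joint) and the anterior radial
fossa.
"""
from __future__ import annotations

from enum import Enum


class RegionLabel(str, Enum):
    PM_HUJ = "pm_huj"          # posteromedial humeroulnar joint (medial olecranon)
    PL_HUJ = "pl_huj"          # posterolateral humeroulnar joint (lateral olecranon)
    POST_CAP = "post_cap"      # posterior capitellum
    ANT_HUJ = "ant_huj"        # anterior humeroulnar joint (coronoid process)
    RAD_FOSSA = "rad_fossa"    # anterior radial fossa

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: regions measured in the simulated full-extension position
EXTENSION_REGIONS = (RegionLabel.PM_HUJ, RegionLabel.PL_HUJ, RegionLabel.POST_CAP)
#: regions measured in the simulated full-flexion position
FLEXION_REGIONS = (RegionLabel.ANT_HUJ, RegionLabel.RAD_FOSSA)

#: cohort-table column name per region
REGION_COLUMNS = {
    RegionLabel.PM_HUJ: "pm_huj_mm",
    RegionLabel.PL_HUJ: "pl_huj_mm",
    RegionLabel.POST_CAP: "post_cap_mm",
    RegionLabel.ANT_HUJ: "ant_huj_mm",
    RegionLabel.RAD_FOSSA: "rad_fossa_mm",
}
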