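"""The 76-region cortical parcellation used for ROI summaries.

38 cortical regions per hemisphere from the AAL anatomical parcellation
(subcortical gray nuclei excluded).  Integer labels run 1..76 in
left/right-interleaved order: label 2*k-1 is the left instance of region k,
label 2*k the right.  The same ordering defines the 152 columns of the
brain matrix (76 T1 columns followed by 76 MD columns).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["REGIONS", "N_ROIS", "label_table", "column_names"]

# (region name, lobe) for the 38 cortical regions per hemisphere
REGIONS: list[tuple[str, str]] = [
    ("Precentral Gyrus", "Frontal"),
    ("Superior Frontal Gyrus: Dorsolateral", "Frontal"),
    ("Superior Frontal Gyrus: Orbital Part", "Frontal"),
    ("Middle Frontal Gyrus", "Frontal"),
    ("Middle Frontal Gyrus: Orbital Part", "Frontal"),
    ("Inferior Frontal Gyrus: Opercular Part", "Frontal"),
    ("Inferior Frontal Gyrus: Triangular Part", "Frontal"),
    ("Inferior Frontal Gyrus: Orbital Part", "Frontal"),
    ("Rolandic Operculum", "Frontal"),
    ("Supplementary Motor Area", "Frontal"),
    ("Superior Frontal Gyrus: Medial", "Frontal"),
    ("Superior Frontal Gyrus: Medial Orbital", "Frontal"),
    ("Gyrus Rectus", "Frontal"),
    ("Paracentral Lobule", "Frontal"),
    ("Insula", "Insula and Cingulate"),
    ("Anterior Cingulate and Paracingulate Gyri", "Insula and Cingulate"),
    ("Median Cingulate and Paracingulate Gyri", "Insula and Cingulate"),
    ("Posterior Cingulate Gyrus", "Insula and Cingulate"),
    ("Parahippocampal Gyrus", "Temporal"),
    ("Calcarine Fissure and Surrounding Cortex", "Occipital"),
    ("Cuneus", "Occipital"),
    ("Lingual Gyrus", "Occipital"),
    ("Superior Occipital Gyrus", "Occipital"),
    ("Middle Occipital Gyrus", "Occipital"),
    ("Inferior Occipital Gyrus", "Occipital"),
    ("Fusiform Gyrus", "Temporal"),
    ("Postcentral Gyrus", "Parietal"),
    ("Superior Parietal Gyrus", "Parietal"),
    ("Inferior Parietal Gyrus", "Parietal"),
    ("Supramarginal Gyrus", "Parietal"),
    ("Angular Gyrus", "Parietal"),
    ("Precuneus", "Parietal"),
    ("Heschl Gyrus", "Temporal"),
    ("Superior Temporal Gyrus", "Temporal"),
    ("Superior Temporal Pole", "Temporal"),
    ("Middle Temporal Gyrus", "Temporal"),
    ("Middle Temporal Pole", "Temporal"),
    ("Inferior Temporal Gyrus", "Temporal"),
]

N_ROIS = 2 * len(REGIONS)  # 76


def label_table() -> pd.DataFrame:
    """Lookup table mapping integer label -> region name, hemisphere, lobe."""
    rows = []
    for k, (name, lobe) in enumerate(REGIONS):
        rows.append({"label": 2 * k + 1, "name": name, "hemisphere": "L", "lobe": lobe})
        rows.append({"label": 2 * k + 2, "name": name, "hemisphere": "R", "lobe": lobe})
    return pd.DataFrame(rows)


def column_names() -> list[str]:
    """The fixed 152 brain-matrix column names: 76 T1 then 76 MD."""
    tab = label_table()
    rois = [f"{h}_{n}" for n, h in zip(tab["name"], tab["hemisphere"])]
    return [f"T1:{r}" for r in rois] + [f"MD:{r}" for r in rois]
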