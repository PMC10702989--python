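"""ROI label metadata.

The two study modalities index features by the 116 parcels of the AAL
(Automated Anatomical Labeling) atlas: 45 left/right cortical and
subcortical pairs, 9 cerebellar hemisphere pairs and 8 vermis parcels.
Any other label set is accepted everywhere; these names are shipped only
as a convenient default for simulated or real AAL-parcellated tables.
"""

from __future__ import annotations

_PAIRED = [
    "Precentral",
    "Frontal_Sup",
    "Frontal_Sup_Orb",
    "Frontal_Mid",
    "Frontal_Mid_Orb",
    "Frontal_Inf_Oper",
    "Frontal_Inf_Tri",
    "Frontal_Inf_Orb",
    "Rolandic_Oper",
    "Supp_Motor_Area",
    "Olfactory",
    "Frontal_Sup_Medial",
    "Frontal_Med_Orb",
    "Rectus",
    "Insula",
    "Cingulum_Ant",
    "Cingulum_Mid",
    "Cingulum_Post",
    "Hippocampus",
    "ParaHippocampal",
    "Amygdala",
    "Calcarine",
    "Cuneus",
    "Lingual",
    "Occipital_Sup",
    "Occipital_Mid",
    "Occipital_Inf",
    "Fusiform",
    "Postcentral",
    "Parietal_Sup",
    "Parietal_Inf",
    "SupraMarginal",
    "Angular",
    "Precuneus",
    "Paracentral_Lobule",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Thalamus",
    "Heschl",
    "Temporal_Sup",
    "Temporal_Pole_Sup",
    "Temporal_Mid",
    "Temporal_Pole_Mid",
    "Temporal_Inf",
    "Cerebelum_Crus1",
    "Cerebelum_Crus2",
    "Cerebelum_3",
    "Cerebelum_4_5",
    "Cerebelum_6",
    "Cerebelum_7b",
    "Cerebelum_8",
    "Cerebelum_9",
    "Cerebelum_10",
]

_VERMIS = [
    "Vermis_1_2",
    "Vermis_3",
    "Vermis_4_5",
    "Vermis_6",
    "Vermis_7",
    "Vermis_8",
    "Vermis_9",
    "Vermis_10",
]

#: The 116 AAL parcel names in atlas order (L/R interleaved, vermis last).
AAL116: list[str] = [
    f"{name}_{side}" for name in _PAIRED for side in ("L", "R")
] + _VERMIS

assert len(AAL116) == 116


def default_roi_labels(n: int) -> list[str]:
    """AAL names when ``n`` == 116, generic ``ROI_001``-style names otherwise."""
    if n == 116:
        return list(AAL116)
    width = max(3, len(str(n)))
    return [f"ROI_{i + 1:0{width}d}" for i in range(n)]
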