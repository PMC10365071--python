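"""Desikan-Killiany cortical parcellation (left hemisphere).

FreeSurfer's ``aparc`` annotation divides each cortical hemisphere into 34
anatomical regions (the Desikan-Killiany atlas).  The biomarker pipeline
operates on the left hemisphere, so one feature vector has exactly 34
entries, one per region, in the canonical FreeSurfer label order below.
"""

from __future__ import annotations

# FreeSurfer aparc label order, corpus callosum / unknown excluded.
DESIKAN_KILLIANY_LH: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

N_ROIS = len(DESIKAN_KILLIANY_LH)
assert N_ROIS == 34


def validate_roi_names(names: list[str] | tuple[str, ...]) -> None:
    """Raise ``ValueError`` if *names* is not the full left-hemisphere atlas."""
    unknown = [n for n in names if n not in DESIKAN_KILLIANY_LH]
    if unknown:
        raise ValueError(f"unknown Desikan-Killiany ROI name(s): {unknown}")
    missing = [n for n in DESIKAN_KILLIANY_LH if n not in set(names)]
    if missing:
        raise ValueError(f"atlas mode requires all 34 ROIs; missing: {missing}")
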