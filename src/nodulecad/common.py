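"""Shared vocabulary for the nodule CADx pipeline.

Attenuation classes are ordered by increasing Hounsfield density, matching
the 1-5 texture score: scores 1-2 are non-solid (ground-glass), 3 is
part-solid, 4-5 are solid.
"""

CLASS_NAMES = ("non-solid", "part-solid", "solid")

#: Canonical integer texture score of an unambiguous member of each class.
CLASS_TRUE_SCORE = {"non-solid": 1, "part-solid": 3, "solid": 5}

#: Orthogonal viewing planes mapped to the volume axis they index.
#: Volumes are stored (z, y, x) with axial slices indexed by z.
VIEW_AXES = {"axial": 0, "coronal": 1, "sagittal": 2}

VIEWS = tuple(VIEW_AXES)
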