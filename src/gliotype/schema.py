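"""Radiomic feature-name schema.

Emulates the pyradiomics naming layout used for conventional-MRI feature
extraction: 107 basic features per sequence (18 first-order, 14 shape, and
75 texture split 24 GLCM + 14 GLDM + 16 GLRLM + 16 GLSZM + 5 NGTDM), plus
1579 filter-derived higher-order features, for 1686 per modality and 3372
across the two sequences.  Only names and counts are produced here — no
image computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

FEATURE_FAMILIES = {
    "firstorder": 18,
    "shape": 14,
    "glcm": 24,
    "gldm": 14,
    "glrlm": 16,
    "glszm": 16,
    "ngtdm": 5,
}

TEXTURE_FAMILIES = ("glcm", "gldm", "glrlm", "glszm", "ngtdm")

#: image filters applied before higher-order extraction
FILTERS = ("wavelet", "square", "squareroot", "logarithm", "exponential", "gradient")


@dataclass
class FeatureSchema:
    """Counts and naming convention for one modality's feature set."""

    family_counts: dict[str, int] = field(
        default_factory=lambda: dict(FEATURE_FAMILIES)
    )
    n_filter_derived: int = 1579
    include_filter_derived: bool = True

    @property
    def n_basic(self) -> int:
        return sum(self.family_counts.values())

    @property
    def n_texture(self) -> int:
        return sum(self.family_counts[f] for f in TEXTURE_FAMILIES)

    @property
    def n_per_modality(self) -> int:
        n = self.n_basic
        if self.include_filter_derived:
            n += self.n_filter_derived
        return n


def feature_schema_names(
    schema: FeatureSchema | None = None,
    modalities: tuple[str, ...] = ("T1CE", "T2FLAIR"),
) -> dict[str, list[str]]:
    """Generate schema-conformant feature names per modality.

    Names follow ``<modality>_<filter>_<class>_<feature>``; basic features
    use the pseudo-filter ``original``.  Filter-derived names cycle through
    the six image filters and the intensity feature families (shape is
    geometry-only and is never recomputed under an image filter).
    """
    schema = schema or FeatureSchema()
    out: dict[str, list[str]] = {}
    for mod in modalities:
        names: list[str] = []
        for family, count in schema.family_counts.items():
            names.extend(
                f"{mod}_original_{family}_f{i:02d}" for i in range(1, count + 1)
            )
        if schema.include_filter_derived:
            intensity = [f for f in schema.family_counts if f != "shape"]
            i = 0
            while len(names) < schema.n_basic + schema.n_filter_derived:
                filt = FILTERS[i % len(FILTERS)]
                family = intensity[(i // len(FILTERS)) % len(intensity)]
                idx = i // (len(FILTERS) * len(intensity)) + 1
                names.append(f"{mod}_{filt}_{family}_d{idx:03d}")
                i += 1
        if len(set(names)) != len(names):
            raise AssertionError("schema produced duplicate names")
        out[mod] = names
    return out
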