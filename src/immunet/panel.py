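"""Marker panel and cell-population archetypes.

The panel emulates a ~30-channel mass-cytometry antibody panel covering the
major PBMC lineages (CD4/CD8 T, gamma-delta T, B, NK, myeloid) plus
functional readouts (cytokines after PMA/ionomycin stimulation, chemokine
receptors), checkpoint molecules, and proliferation.  Archetypes are the
"true" cell populations the synthetic generator draws events from; each is
defined by the set of markers it expresses so that populations are
separable after the asinh5 transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# role categories for panel markers
LINEAGE = "lineage"
FUNCTIONAL = "functional"
PROLIFERATION = "proliferation"
CHECKPOINT = "checkpoint"

#: Default marker panel: (name, role).  Reconstructed from the subset
#: phenotype labels used throughout the analysis; approximate, since the
#: full instrument panel is not part of the public record.
DEFAULT_PANEL_SPEC: tuple[tuple[str, str], ...] = (
    ("CD45", LINEAGE),
    ("CD3", LINEAGE),
    ("CD4", LINEAGE),
    ("CD8", LINEAGE),
    ("CD14", LINEAGE),
    ("CD15", LINEAGE),
    ("CD19", LINEAGE),
    ("CD25", FUNCTIONAL),
    ("CD56", LINEAGE),
    ("CD45RA", LINEAGE),
    ("FoxP3", FUNCTIONAL),
    ("CD152", CHECKPOINT),   # CTLA4
    ("PD1", CHECKPOINT),
    ("TIGIT", CHECKPOINT),
    ("CX3CR1", FUNCTIONAL),
    ("CXCR3", FUNCTIONAL),
    ("CCR4", FUNCTIONAL),
    ("CD160", FUNCTIONAL),
    ("CD244", FUNCTIONAL),
    ("HLA-DR", LINEAGE),
    ("TCRgd", LINEAGE),
    ("Tbet", FUNCTIONAL),
    ("GATA3", FUNCTIONAL),
    ("Ki67", PROLIFERATION),
    ("IL17A", FUNCTIONAL),
    ("IL4", FUNCTIONAL),
    ("IL8", FUNCTIONAL),
    ("TNFa", FUNCTIONAL),
    ("IFNg", FUNCTIONAL),
    ("GranzymeB", FUNCTIONAL),
)

LINEAGES = ("CD4 T", "CD8 T", "gdT", "B", "NK", "myeloid", "other")


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered marker panel with a lineage-role map.

    Parameters
    ----------
    markers : tuple of str
        Unique channel names, in acquisition order.
    lineage_map : dict
        Marker name -> role, one of {lineage, functional, proliferation,
        checkpoint}.
    """

    markers: tuple[str, ...]
    lineage_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker names must be unique")
        unknown = set(self.lineage_map) - set(self.markers)
        if unknown:
            raise ValueError(f"lineage_map names absent from panel: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.markers)

    def index(self, marker: str) -> int:
        return self.markers.index(marker)


def default_panel() -> MarkerPanel:
    """The default ~30-marker PBMC panel."""
    return MarkerPanel(
        markers=tuple(name for name, _ in DEFAULT_PANEL_SPEC),
        lineage_map={name: role for name, role in DEFAULT_PANEL_SPEC},
    )


# Raw-intensity location defaults (dimensionless dual counts).  A marker a
# population expresses sits around POS_LEVEL; unexpressed markers produce
# low-level background.  CD45 is bright on every PBMC.
POS_LEVEL = 180.0
BRIGHT_LEVEL = 400.0
NEG_LEVEL = 0.6
POS_SIGMA = 0.45     # lognormal shape for expressed markers
NEG_SIGMA = 0.8
POS_DROPOUT = 0.05   # zero-inflation probabilities
NEG_DROPOUT = 0.70


@dataclass(frozen=True)
class PopulationArchetype:
    """A true cell population: raw-scale intensity model per marker.

    ``mean_raw``/``dispersion``/``dropout`` parameterise a zero-inflated
    lognormal per channel: an event is 0 with probability ``dropout``,
    otherwise LogNormal(log(mean_raw), dispersion).
    """

    name: str
    lineage: str
    mean_raw: np.ndarray
    dispersion: np.ndarray
    dropout: np.ndarray

    def __post_init__(self):
        if self.lineage not in LINEAGES:
            raise ValueError(f"unknown lineage {self.lineage!r}")
        if np.any(np.asarray(self.mean_raw) < 0):
            raise ValueError("mean_raw must be non-negative")


def make_archetype(
    name: str,
    lineage: str,
    positive: tuple[str, ...],
    panel: MarkerPanel,
    bright: tuple[str, ...] = (),
) -> PopulationArchetype:
    """Build an archetype from the set of markers it expresses."""
    pos = set(positive) | {"CD45"}
    unknown = (pos | set(bright)) - set(panel.markers)
    if unknown:
        raise ValueError(f"markers not in panel: {sorted(unknown)}")
    mean = np.full(len(panel), NEG_LEVEL)
    disp = np.full(len(panel), NEG_SIGMA)
    drop = np.full(len(panel), NEG_DROPOUT)
    for m in pos:
        i = panel.index(m)
        mean[i] = BRIGHT_LEVEL if m in bright or m == "CD45" else POS_LEVEL
        disp[i] = POS_SIGMA
        drop[i] = POS_DROPOUT
    return PopulationArchetype(name, lineage, mean, disp, drop)


#: (name, lineage, expressed markers).  First 4 = subsets enriched in
#: sepsis, next 7 = depleted, remainder = stable fillers.  The final
#: archetype is a doublet-like CD3+CD19+ mixed population that the
#: mixed-cluster exclusion rule is expected to flag.
DEFAULT_ARCHETYPE_SPEC: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    ("CD15+CD14+ monocytes", "myeloid", ("CD14", "CD15", "HLA-DR", "IL8", "TNFa")),
    ("CD45RA-CX3CR1+CTLA4+CD4+ T", "CD4 T", ("CD3", "CD4", "CX3CR1", "CD152", "CXCR3", "TNFa")),
    ("CD45RA-IL17A+CD4+ T", "CD4 T", ("CD3", "CD4", "IL17A", "CCR4", "TNFa")),
    ("Ki67+ B", "B", ("CD19", "HLA-DR", "Ki67")),
    ("FOXP3+CD25+CD152+ naive Treg", "CD4 T", ("CD3", "CD4", "CD45RA", "FoxP3", "CD25", "CD152")),
    ("temra CD4", "CD4 T", ("CD3", "CD4", "CD45RA", "Tbet", "GranzymeB", "CD244")),
    ("temra CD8", "CD8 T", ("CD3", "CD8", "CD45RA", "Tbet", "GranzymeB", "CD244", "IFNg")),
    ("GATA3+CD56++ NK", "NK", ("GATA3", "IL4")),
    ("Lin-HLADR+IL8+", "other", ("HLA-DR", "IL8")),
    ("IL8+ naive CD8", "CD8 T", ("CD3", "CD8", "CD45RA", "IL8")),
    ("IL8+ naive CD4", "CD4 T", ("CD3", "CD4", "CD45RA", "IL8")),
    ("naive CD4", "CD4 T", ("CD3", "CD4", "CD45RA")),
    ("naive CD8", "CD8 T", ("CD3", "CD8", "CD45RA")),
    ("central memory CD4", "CD4 T", ("CD3", "CD4", "CCR4", "CXCR3")),
    ("PD1+CD152+TIGIT+ em CD4", "CD4 T", ("CD3", "CD4", "PD1", "CD152", "TIGIT")),
    ("classical monocytes", "myeloid", ("CD14", "HLA-DR", "TNFa")),
    ("CD56+ NK", "NK", ("GranzymeB", "IFNg", "CD160")),
    ("memory B", "B", ("CD19", "HLA-DR", "CXCR3")),
    ("Tbet+GB+CX3CR1+CXCR3+ gdT", "gdT", ("CD3", "TCRgd", "Tbet", "GranzymeB", "CX3CR1", "CXCR3")),
    ("CD3+CD19+ mixed", "other", ("CD3", "CD19", "HLA-DR")),
)


def default_archetypes(panel: MarkerPanel | None = None) -> list[PopulationArchetype]:
    """The 20 default archetypes (11 differential + 8 fillers + 1 mixed)."""
    panel = panel or default_panel()
    out = []
    for name, lineage, positive in DEFAULT_ARCHETYPE_SPEC:
        bright = ("CD56",) if "CD56++" in name else ()
        pos = positive + (("CD56",) if "NK" in lineage or "CD56" in name else ())
        arch = make_archetype(name, lineage, pos, panel, bright=bright)
        if name == "CD3+CD19+ mixed":
            # doublet-like events are phenotypically stereotyped (two cells
            # contributing a fixed signature), so the mixed population is
            # tighter than true populations
            arch = PopulationArchetype(
                arch.name, arch.lineage, arch.mean_raw,
                arch.dispersion * 0.5, arch.dropout * 0.4,
            )
        out.append(arch)
    return out


def centroid_separation(archetypes, cofactor: float = 5.0) -> float:
    """Smallest pairwise Euclidean distance between asinh-transformed
    archetype centroids (positivity-weighted means of the intensity model)."""
    centroids = np.array(
        [np.arcsinh(a.mean_raw / cofactor) * (1 - a.dropout) for a in archetypes]
    )
    n = len(centroids)
    dmin = np.inf
    for i in range(n):
        for j in range(i + 1, n):
            dmin = min(dmin, float(np.linalg.norm(centroids[i] - centroids[j])))
    return dmin
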