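"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the statistical structure of the study's
inputs: 7-TM receptor families with controlled extracellular-loop
divergence from a common template (standing in for the screened GPCR
pool), 4PL dose-response plates with replicate noise, and multi-channel
puncta fields with a known colocalized fraction.  Every generator is a
pure function of its spec, including the seed.

TM residues are drawn from the strongly hydrophobic set and loop
residues from a hydrophilic set, so the default Kyte–Doolittle topology
caller recovers the true topology exactly — topology recovery is a
testable invariant, not an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coloc import ChannelImage
from .pharm import DoseResponseDataset, four_pl
from .records import ProteinRecord
from .screen import (
    ReferenceBindingDomains,
    SegmentSet,
    extract_extracellular_segments,
    segments_to_reference,
)
from .topology import TopologyAnnotation, annotation_from_labels

#: Strongly hydrophobic residues (positive Kyte-Doolittle values).
TM_RESIDUES = "LIVFAM"
#: Hydrophilic residues (negative Kyte-Doolittle values).
LOOP_RESIDUES = "RKDENQSTGH"


# ---------------------------------------------------------------------------
# receptor families


@dataclass
class FamilySpec:
    """Parameters of a synthetic 7-TM receptor family.

    ``loop_divergence`` is the per-site substitution probability in the
    extramembrane regions (a single float, or one value per candidate);
    ``tm_divergence`` is the per-site rate inside TM helices, where
    substitutions stay within the hydrophobic class.
    """

    n_candidates: int = 20
    loop_divergence: float | Sequence[float] = 0.2
    tm_divergence: float = 0.05
    n_tm: int = 7
    tm_length: int = 21
    nterm_length: int = 30
    loop_length: int = 12
    cterm_length: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_candidates < 1 or self.n_tm < 1:
            raise ValueError("counts must be >= 1")
        for p in list(self.divergences()) + [self.tm_divergence]:
            if not 0.0 <= p <= 1.0:
                raise ValueError("substitution probabilities must lie in [0, 1]")

    def divergences(self) -> list[float]:
        if isinstance(self.loop_divergence, (int, float)):
            return [float(self.loop_divergence)] * self.n_candidates
        divs = [float(p) for p in self.loop_divergence]
        if len(divs) != self.n_candidates:
            raise ValueError("loop_divergence sequence must have n_candidates entries")
        return divs


@dataclass(frozen=True)
class ReceptorFamily:
    """A generated family plus its ground truth."""

    template: ProteinRecord
    template_topology: TopologyAnnotation
    candidates: tuple[ProteinRecord, ...]
    topologies: dict[str, TopologyAnnotation]
    reference_cck1r: ReferenceBindingDomains
    reference_cck2r: ReferenceBindingDomains
    divergences: tuple[float, ...]


def _template_layout(spec: FamilySpec) -> list[tuple[str, int]]:
    """Alternating (label, length) blocks: E-NTERM, 7x TM with E/I loops, tail."""
    layout: list[tuple[str, int]] = [("E", spec.nterm_length)]
    side = "I"  # first loop after TM1 is intracellular
    for i in range(spec.n_tm):
        layout.append(("M", spec.tm_length))
        if i < spec.n_tm - 1:
            layout.append((side, spec.loop_length))
            side = "E" if side == "I" else "I"
    layout.append((side, spec.cterm_length))
    return layout


def make_receptor_family(spec: FamilySpec) -> ReceptorFamily:
    """Generate a template receptor and diverged candidates.

    The template's extracellular segments double as the reference
    binding domains for both screening references, so a candidate's
    true screen score is directly controlled by its loop divergence.
    """
    rng = np.random.default_rng(spec.seed)
    layout = _template_layout(spec)
    labels = "".join(lab * length for lab, length in layout)
    template_seq = "".join(
        "".join(
            rng.choice(list(TM_RESIDUES if lab == "M" else LOOP_RESIDUES))
            for _ in range(length)
        )
        for lab, length in layout
    )
    template = ProteinRecord(id="TEMPLATE", residues=template_seq)
    template_topology = annotation_from_labels(template, labels)
    template_segments = extract_extracellular_segments(template_topology, template)

    divergences = spec.divergences()
    candidates = []
    topologies: dict[str, TopologyAnnotation] = {}
    for idx, p_loop in enumerate(divergences):
        seq = list(template_seq)
        for pos, lab in enumerate(labels):
            if lab == "M":
                p, pool = spec.tm_divergence, TM_RESIDUES
            else:
                p, pool = p_loop, LOOP_RESIDUES
            if p > 0 and rng.random() < p:
                choices = [r for r in pool if r != seq[pos]]
                seq[pos] = choices[rng.integers(len(choices))]
        cid = f"CAND{idx:03d}"
        rec = ProteinRecord(id=cid, residues="".join(seq))
        candidates.append(rec)
        topologies[cid] = annotation_from_labels(rec, labels)

    ref1 = segments_to_reference(template_segments, "CCK1R")
    ref2 = segments_to_reference(template_segments, "CCK2R")
    return ReceptorFamily(
        template=template,
        template_topology=template_topology,
        candidates=tuple(candidates),
        topologies=topologies,
        reference_cck1r=ref1,
        reference_cck2r=ref2,
        divergences=tuple(divergences),
    )


# ---------------------------------------------------------------------------
# dose-response plates

#: Half-log dose grid from 0.01 to 1000 nM.
DEFAULT_DOSES_NM = tuple(float(10.0 ** e) for e in np.arange(-2.0, 3.01, 0.5))


@dataclass
class PlateSpec:
    """Parameters of a synthetic dose-response plate.

    ``noise`` is interpreted per ``noise_model``: 'cv' applies
    multiplicative Gaussian noise with that coefficient of variation,
    'sd' additive Gaussian noise with that SD (assay units).
    """

    ec50_nM: float = 3.23
    hill: float = 1.0
    bottom: float = 1.0
    top: float = 3.0
    doses_nM: Sequence[float] = DEFAULT_DOSES_NM
    replicates: int = 3
    noise: float = 0.05
    noise_model: str = "cv"
    mode: str = "agonist"
    seed: int = 0

    def __post_init__(self):
        if self.ec50_nM <= 0:
            raise ValueError("EC50 must be positive")
        if len(self.doses_nM) < 4:
            raise ValueError("need at least 4 doses")
        if self.noise_model not in ("cv", "sd"):
            raise ValueError("noise_model must be 'cv' or 'sd'")
        if self.mode not in ("agonist", "antagonist"):
            raise ValueError("mode must be 'agonist' or 'antagonist'")
        if self.replicates < 1:
            raise ValueError("need at least one replicate per dose")


def make_dose_response(spec: PlateSpec) -> DoseResponseDataset:
    """Forward-4PL plate with per-replicate seeded noise.

    Antagonist mode produces a decreasing curve whose midpoint is the
    spec's IC50.
    """
    rng = np.random.default_rng(spec.seed)
    hill = abs(spec.hill) if spec.mode == "agonist" else -abs(spec.hill)
    doses = tuple(float(d) for d in spec.doses_nM)
    clean = four_pl(np.array(doses), spec.bottom, spec.top, np.log10(spec.ec50_nM), hill)
    responses = []
    for mu in clean:
        if spec.noise == 0:
            reps = tuple(float(mu) for _ in range(spec.replicates))
        elif spec.noise_model == "cv":
            reps = tuple(
                float(mu * (1.0 + spec.noise * rng.standard_normal()))
                for _ in range(spec.replicates)
            )
        else:
            reps = tuple(
                float(mu + spec.noise * rng.standard_normal())
                for _ in range(spec.replicates)
            )
        responses.append(reps)
    return DoseResponseDataset(
        doses=doses,
        responses=tuple(responses),
        mode=spec.mode,
        fixed_agonist_dose_nM=10.0 if spec.mode == "antagonist" else None,
    )


# ---------------------------------------------------------------------------
# colocalization image fields


@dataclass
class ImageSpec:
    """Parameters of a synthetic multi-channel puncta field.

    A fraction ``coloc_fraction`` of the puncta in channels 2 (and 3)
    is planted coincident with channel-1 positions up to a Gaussian
    localization jitter; the rest are placed independently.  Planted
    puncta within a channel keep a minimum separation so ground-truth
    identity stays well defined.
    """

    size_px: int = 256
    pixel_size_um: float = 0.05
    n_puncta: int = 60
    n_channels: int = 2
    coloc_fraction: float = 0.5
    spot_sigma_px: float = 2.0
    peak: float = 10.0
    noise_sd: float = 1.0
    background_level: float = 5.0
    jitter_px: float = 1.0
    min_separation_px: float = 10.0
    margin_px: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if self.n_puncta < 0:
            raise ValueError("n_puncta must be >= 0")
        if self.n_channels not in (2, 3):
            raise ValueError("n_channels must be 2 or 3")


@dataclass(frozen=True)
class ColocField:
    """Generated channels plus planted ground truth."""

    channels: tuple[ChannelImage, ...]
    true_positions: tuple[np.ndarray, ...]  # (n, 2) row/col per channel, px
    n_coincident: int
    coincident_indices: tuple[int, ...]  # indices shared by all channels

    @property
    def field_area_mm2(self) -> float:
        return self.channels[0].field_area_mm2


def _sample_positions(
    rng: np.random.Generator,
    n: int,
    size: float,
    margin: float,
    min_sep: float,
    existing: list[np.ndarray],
) -> list[np.ndarray]:
    placed = list(existing)
    out = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("could not place puncta with the requested separation")
        pos = rng.uniform(margin, size - margin, size=2)
        if all(np.linalg.norm(pos - q) >= min_sep for q in placed):
            placed.append(pos)
            out.append(pos)
    return out


def _render(
    positions: np.ndarray, spec: ImageSpec, rng: np.random.Generator
) -> np.ndarray:
    size = spec.size_px
    img = np.full((size, size), float(spec.background_level))
    rows = np.arange(size)[:, None]
    cols = np.arange(size)[None, :]
    for r, c in positions:
        d2 = (rows - r) ** 2 + (cols - c) ** 2
        img += spec.peak * np.exp(-d2 / (2.0 * spec.spot_sigma_px**2))
    if spec.noise_sd > 0:
        img += spec.noise_sd * rng.standard_normal((size, size))
    return np.clip(img, 0.0, None)


def make_coloc_images(spec: ImageSpec) -> ColocField:
    """Render 2- or 3-channel puncta fields with known coincidences."""
    rng = np.random.default_rng(spec.seed)
    size, margin, sep = float(spec.size_px), spec.margin_px, spec.min_separation_px
    n_coloc = int(round(spec.coloc_fraction * spec.n_puncta))

    pos1 = _sample_positions(rng, spec.n_puncta, size, margin, sep, [])
    all_positions = [np.array(pos1).reshape(-1, 2)]
    for _ in range(spec.n_channels - 1):
        coincident = []
        for idx in range(n_coloc):
            jitter = rng.normal(0.0, spec.jitter_px, size=2) if spec.jitter_px > 0 else 0.0
            coincident.append(np.clip(pos1[idx] + jitter, 0.0, size - 1.0))
        independent = _sample_positions(
            rng, spec.n_puncta - n_coloc, size, margin, sep, coincident
        )
        all_positions.append(np.array(coincident + independent).reshape(-1, 2))

    names = ("ch1", "ch2", "ch3")
    channels = tuple(
        ChannelImage(
            pixels=_render(pos, spec, rng),
            pixel_size_um=spec.pixel_size_um,
            name=names[i],
        )
        for i, pos in enumerate(all_positions)
    )
    return ColocField(
        channels=channels,
        true_positions=tuple(all_positions),
        n_coincident=n_coloc,
        coincident_indices=tuple(range(n_coloc)),
    )
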