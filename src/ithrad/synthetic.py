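"""Synthetic CT-like phantoms and cohorts with known ground truth.

Every downstream stage of the pipeline is exercised on data produced
here, because the patient cohorts the method was designed for are not
publicly distributable.  The generator emulates:

* single-lesion tumors composed of ``V`` spatial habitats, each habitat
  split into a controlled number of connected fragments occupying a
  controlled share of the tumor area (so the ground-truth ITH-score is
  known by construction);
* per-habitat texture as a Gaussian random field (mean intensity, noise
  sd, spatial correlation length) — the simplest texture whose habitats
  are separable by local first-order and co-occurrence features;
* scanner batches as image-level location/scale shifts;
* a second, boundary-perturbed segmentation of each lesion, standing in
  for a repeat reading in segmentation-stability (ICC) filtering;
* distant-metastasis-free survival from an exponential proportional-
  hazards model whose log-hazard loads on the true heterogeneity and on
  selected clinical covariates, censored by uniform dropout and an
  administrative horizon.

All randomness descends from one integer seed through numpy's
``SeedSequence`` spawning, so fixed seeds give bit-identical output.
"""

from __future__ import annotations

import dataclasses
import heapq
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import ImageVolume, ROIMask, save_nifti
from .ith import ith_score_of_labels

__all__ = [
    "TextureParams",
    "PhantomSpec",
    "TrueLabelMap",
    "PhenotypeTemplate",
    "CohortSpec",
    "SyntheticSubject",
    "SyntheticCohort",
    "generate_texture_phantom",
    "perturb_mask",
    "generate_cohort",
    "true_ith_closed_form",
    "expected_event_fraction",
]


@dataclasses.dataclass
class TextureParams:
    """Gaussian-random-field texture of one habitat (HU-like units)."""

    mean: float
    sd: float = 5.0
    corr_length: float = 2.0


@dataclasses.dataclass
class PhantomSpec:
    """Blueprint for one textured tumor phantom."""

    grid_shape: tuple[int, int] = (48, 48)
    n_habitats: int = 2
    habitat_fragments: tuple[int, ...] = (1, 1)
    area_fractions: tuple[float, ...] = (0.5, 0.5)
    texture_params: tuple[TextureParams, ...] | None = None
    #: smooth center-to-rim intensity drift (HU over the lesion radius),
    #: emulating the peripheral enhancement gradient of contrast-enhanced
    #: lesions; gives even habitat-free tumors large-scale structure
    radial_gradient: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_habitats < 1:
            raise ValueError("n_habitats must be >= 1")
        if len(self.habitat_fragments) != self.n_habitats:
            raise ValueError("habitat_fragments length must equal n_habitats")
        if len(self.area_fractions) != self.n_habitats:
            raise ValueError("area_fractions length must equal n_habitats")
        if any(f < 1 for f in self.habitat_fragments):
            raise ValueError("each habitat needs at least 1 fragment")
        if abs(sum(self.area_fractions) - 1.0) > 1e-9:
            raise ValueError("area_fractions must sum to 1")
        if any(f <= 0 for f in self.area_fractions):
            raise ValueError("area_fractions must be positive")
        if self.texture_params is None:
            # evenly spaced mean intensities, separable by local features
            self.texture_params = tuple(
                TextureParams(mean=40.0 + 35.0 * i) for i in range(self.n_habitats)
            )
        if len(self.texture_params) != self.n_habitats:
            raise ValueError("texture_params length must equal n_habitats")


@dataclasses.dataclass
class TrueLabelMap:
    """Ground-truth habitat labels: 0 outside the mask, 1..V inside."""

    labels: np.ndarray
    n_habitats: int

    def true_ith(self, connectivity: int = 4) -> float:
        return ith_score_of_labels(self.labels, connectivity=connectivity)


_N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


def _disk_mask(shape: tuple[int, int]) -> np.ndarray:
    r0, c0 = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    radius = 0.42 * min(shape)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2


_N8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


def _grow_partition(
    mask: np.ndarray,
    targets: list[int],
    seeds: list[tuple[int, int]],
    frag_habitat: list[int] | None = None,
) -> np.ndarray:
    """Capacity-constrained multi-source region growing.

    Each fragment grows from its seed pixel by claiming the unclaimed
    in-mask pixel nearest (Euclidean) to the seed among its frontier, the
    most size-deficient fragment moving first.  Claimed sets stay connected
    because every new pixel adjoins the existing set.  When
    ``frag_habitat`` is given, a fragment never claims a pixel 8-adjacent
    to a *different* fragment of the same habitat, which keeps same-habitat
    fragments separated by at least a one-pixel moat of other habitats.
    Leftover pixels (fragments walled off early) are attached to an
    adjacent fragment at the end.
    """
    if frag_habitat is None:
        frag_habitat = list(range(len(targets)))
    owner = np.full(mask.shape, -1, dtype=int)

    def violates(f: int, r: int, c: int) -> bool:
        for dr, dc in _N8:
            nr, nc = r + dr, c + dc
            if 0 <= nr < mask.shape[0] and 0 <= nc < mask.shape[1]:
                g = owner[nr, nc]
                if g >= 0 and g != f and frag_habitat[g] == frag_habitat[f]:
                    return True
        return False

    heaps: list[list] = [[] for _ in targets]
    sizes = [0] * len(targets)
    counter = 0
    for f, (r, c) in enumerate(seeds):
        heapq.heappush(heaps[f], (0.0, counter, (r, c)))
        counter += 1
    while True:
        cands = [
            f for f in range(len(targets))
            if sizes[f] < targets[f] and heaps[f]
        ]
        if not cands:
            break
        f = max(cands, key=lambda q: (targets[q] - sizes[q]) / targets[q])
        claimed = None
        while heaps[f]:
            _, _, (r, c) = heapq.heappop(heaps[f])
            if owner[r, c] == -1 and not violates(f, r, c):
                claimed = (r, c)
                break
        if claimed is None:
            continue
        r, c = claimed
        owner[r, c] = f
        sizes[f] += 1
        sr, sc = seeds[f]
        for dr, dc in _N4:
            nr, nc = r + dr, c + dc
            if 0 <= nr < mask.shape[0] and 0 <= nc < mask.shape[1]:
                if mask[nr, nc] and owner[nr, nc] == -1:
                    dist = float((nr - sr) ** 2 + (nc - sc) ** 2)
                    heapq.heappush(heaps[f], (dist, counter, (nr, nc)))
                    counter += 1
    # attach any leftover pixels to a neighboring fragment, still honoring
    # the same-habitat moat where possible
    while True:
        left = np.argwhere(mask & (owner == -1))
        if len(left) == 0:
            break
        progressed = False
        for r, c in left:
            neigh = {
                owner[r + dr, c + dc]
                for dr, dc in _N4
                if 0 <= r + dr < mask.shape[0] and 0 <= c + dc < mask.shape[1]
                and owner[r + dr, c + dc] >= 0
            }
            if not neigh:
                continue
            ok = [f for f in neigh if not violates(f, r, c)]
            pool = ok if ok else list(neigh)
            owner[r, c] = max(pool, key=lambda f: targets[f] - sizes[f])
            sizes[owner[r, c]] += 1
            progressed = True
        if not progressed:  # pragma: no cover - mask is connected, cannot happen
            raise RuntimeError("partition failed to cover the mask")
    return owner


def _partition_ok(
    labels: np.ndarray, spec: PhantomSpec, s_total: int
) -> bool:
    structure = ndimage.generate_binary_structure(2, 1)
    for i in range(spec.n_habitats):
        binary = labels == i + 1
        area = int(binary.sum())
        if abs(area - spec.area_fractions[i] * s_total) > 0.02 * s_total:
            return False
        _, n = ndimage.label(binary, structure=structure)
        if n != spec.habitat_fragments[i]:
            return False
    return True


def _gaussian_field(shape, corr_length, rng) -> np.ndarray:
    white = rng.standard_normal(shape)
    if corr_length > 0:
        field = ndimage.gaussian_filter(white, sigma=corr_length)
    else:
        field = white
    sd = field.std()
    return field / sd if sd > 0 else field


def _make_partition(spec: PhantomSpec, geom_ss: np.random.SeedSequence
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Disk mask plus habitat labels honoring fragments/fractions.

    Per-fragment pixel targets are an equal split of the habitat's share;
    random seed placements are retried until every habitat realizes its
    requested fragment count and its area lands within 2% of the tumor
    area.
    """
    mask = _disk_mask(spec.grid_shape)
    s_total = int(mask.sum())
    n_frag = sum(spec.habitat_fragments)
    if n_frag > s_total:
        raise ValueError(
            f"{n_frag} fragments cannot fit in a {s_total}-pixel lesion"
        )
    targets: list[int] = []
    frag_habitat: list[int] = []
    for i in range(spec.n_habitats):
        per = spec.area_fractions[i] * s_total / spec.habitat_fragments[i]
        for _ in range(spec.habitat_fragments[i]):
            targets.append(max(1, int(round(per))))
            frag_habitat.append(i + 1)
    # distribute rounding remainder over the largest fragments
    drift = s_total - sum(targets)
    order = np.argsort(targets)[::-1]
    j = 0
    while drift != 0:
        targets[order[j % len(targets)]] += 1 if drift > 0 else -1
        drift += -1 if drift > 0 else 1
        j += 1

    # spread each habitat's fragments evenly around the lesion: slots are
    # ordered by their ideal angular position, so that once seeds are
    # sorted by angle, fragments of one habitat sit far apart and do not
    # merge during growth
    by_hab: dict[int, list[int]] = {}
    for slot, hab in enumerate(frag_habitat):
        by_hab.setdefault(hab, []).append(slot)
    placed: list[tuple[float, int]] = []
    for hab, slots in by_hab.items():
        m = len(slots)
        for j, slot in enumerate(slots):
            placed.append(((j + 0.5) / m + 1e-3 * hab, slot))
    slot_order = [slot for _, slot in sorted(placed)]

    coords = np.argwhere(mask)
    centroid = coords.mean(axis=0)
    for attempt in range(200):
        rng = np.random.default_rng(geom_ss)
        pick = rng.choice(len(coords), size=n_frag, replace=False)
        pts = coords[pick]
        angles = np.arctan2(pts[:, 0] - centroid[0], pts[:, 1] - centroid[1])
        pts = pts[np.argsort(angles)]
        seeds: list[tuple[int, int]] = [None] * n_frag  # type: ignore[list-item]
        for pos, slot in enumerate(slot_order):
            seeds[slot] = tuple(pts[pos])
        owner = _grow_partition(mask, targets, seeds, frag_habitat)
        cand = np.zeros(mask.shape, dtype=int)
        for f, hab in enumerate(frag_habitat):
            cand[owner == f] = hab
        if _partition_ok(cand, spec, s_total):
            return mask, cand
        geom_ss = geom_ss.spawn(1)[0]
    raise RuntimeError(
        "could not realize the requested fragmentation; relax the spec"
    )


def generate_texture_phantom(
    spec: PhantomSpec,
) -> tuple[ImageVolume, ROIMask, TrueLabelMap]:
    """Build one textured tumor phantom from its spec.

    The lesion is a disk; habitats are grown as capacity-constrained
    regions so that habitat ``i`` covers its requested area fraction
    (within 2% of the tumor area) in exactly ``habitat_fragments[i]``
    connected pieces, each fragment taking an equal share of the habitat.
    Texture inside each habitat is an independent Gaussian random field.
    """
    ss = np.random.SeedSequence(spec.seed)
    geom_ss, tex_ss, bg_ss = ss.spawn(3)
    mask, labels = _make_partition(spec, geom_ss)

    image = 2.0 * _gaussian_field(spec.grid_shape, 1.0, np.random.default_rng(bg_ss))
    children = tex_ss.spawn(spec.n_habitats)
    for i, tp in enumerate(spec.texture_params):
        field = _gaussian_field(
            spec.grid_shape, tp.corr_length, np.random.default_rng(children[i])
        )
        hab = labels == i + 1
        image[hab] = tp.mean + tp.sd * field[hab]
    if spec.radial_gradient != 0.0:
        rr, cc = np.mgrid[: spec.grid_shape[0], : spec.grid_shape[1]]
        r0 = coords_mean = np.argwhere(mask).mean(axis=0)
        dist = np.hypot(rr - r0[0], cc - r0[1])
        dist = dist / max(dist[mask].max(), 1e-9)
        image[mask] += spec.radial_gradient * dist[mask]
    return (
        ImageVolume(image),
        ROIMask(mask),
        TrueLabelMap(labels=labels, n_habitats=spec.n_habitats),
    )


def perturb_mask(mask: ROIMask, magnitude: float, seed: int = 0) -> ROIMask:
    """Morphological boundary perturbation of a segmentation.

    The mask's signed distance field is shifted by a smooth random field
    scaled so the boundary moves by at most ``magnitude`` pixels; overlap
    with the input therefore decreases smoothly as magnitude grows.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if mask.is_empty():
        raise ValueError("mask is empty")
    if magnitude == 0:
        return ROIMask(mask.data.copy(), mask.spacing)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    signed = ndimage.distance_transform_edt(mask.data) - ndimage.distance_transform_edt(
        ~mask.data
    )
    noise = ndimage.gaussian_filter(rng.standard_normal(mask.data.shape), sigma=3.0)
    peak = np.abs(noise).max()
    if peak > 0:
        noise = noise / peak
    out = (signed + magnitude * noise) > 0
    if not out.any():
        raise ValueError("perturbation emptied the mask; reduce magnitude")
    # keep a single lesion: retain the largest connected component
    comp, n = ndimage.label(out)
    if n > 1:
        sizes = np.bincount(comp.ravel())[1:]
        out = comp == (int(np.argmax(sizes)) + 1)
    return ROIMask(out, mask.spacing)


# ---------------------------------------------------------------------------
# cohorts


@dataclasses.dataclass
class PhenotypeTemplate:
    """How lesions of one phenotype are fragmented and textured."""

    n_habitats: int
    fragments_low: int
    fragments_high: int
    dirichlet_alpha: float = 5.0
    mean_spread: float = 35.0
    noise_sd: float = 5.0
    corr_length: float = 2.0


LOW_ITH_TEMPLATE = PhenotypeTemplate(n_habitats=2, fragments_low=1, fragments_high=1)
HIGH_ITH_TEMPLATE = PhenotypeTemplate(n_habitats=4, fragments_low=2, fragments_high=4)


@dataclasses.dataclass
class CohortSpec:
    """Blueprint for a synthetic patient cohort.

    Survival follows an exponential proportional-hazards model
    ``h(t|x) = h0 * exp(beta_ith * ITH_true + beta_cystic * cystic +
    beta_tstage * T)``, censored at ``min(dropout, horizon)`` with dropout
    uniform on (0, 2*horizon).  The prevalence default (83/274, about 30%) is a typical pooled
    distant-metastasis rate for surgically resected retroperitoneal
    sarcoma cohorts.
    """

    n_subjects: int = 100
    prevalence: float = 83 / 274
    beta_ith: float = 1.5
    beta_cystic: float = 0.0
    beta_tstage: float = 0.0
    baseline_hazard: float = 0.015   # events per month
    horizon: float = 60.0            # months of administrative follow-up
    n_batches: int = 1
    batch_loc_shifts: tuple[float, ...] | None = None
    batch_scale_shifts: tuple[float, ...] | None = None
    mask_perturb_magnitude: float = 1.0
    grid_shape: tuple[int, int] = (40, 40)
    with_images: bool = True
    low_template: PhenotypeTemplate = dataclasses.field(
        default_factory=lambda: dataclasses.replace(LOW_ITH_TEMPLATE))
    high_template: PhenotypeTemplate = dataclasses.field(
        default_factory=lambda: dataclasses.replace(HIGH_ITH_TEMPLATE))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.batch_loc_shifts is None:
            self.batch_loc_shifts = tuple(12.0 * b for b in range(self.n_batches))
        if self.batch_scale_shifts is None:
            self.batch_scale_shifts = tuple(
                1.0 + 0.15 * b for b in range(self.n_batches)
            )
        if len(self.batch_loc_shifts) != self.n_batches:
            raise ValueError("batch_loc_shifts length must equal n_batches")
        if len(self.batch_scale_shifts) != self.n_batches:
            raise ValueError("batch_scale_shifts length must equal n_batches")


@dataclasses.dataclass
class SyntheticSubject:
    subject_id: str
    batch: int
    phenotype: int                      # 1 = high-ITH, 0 = low-ITH
    image: ImageVolume | None
    mask: ROIMask | None
    mask_perturbed: ROIMask | None
    true_labels: TrueLabelMap | None
    true_ith: float
    age: float
    sex: int
    t_stage: int
    cystic_necrosis: int
    time_months: float
    event: int
    latent_event_time: float


@dataclasses.dataclass
class SyntheticCohort:
    spec: CohortSpec
    subjects: list[SyntheticSubject]

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": s.subject_id,
                "batch": s.batch,
                "age": s.age,
                "sex": s.sex,
                "t_stage": s.t_stage,
                "cystic_necrosis": s.cystic_necrosis,
                "time_months": s.time_months,
                "event": s.event,
                "true_ith": s.true_ith,
                "true_phenotype": s.phenotype,
                "latent_event_time": s.latent_event_time,
            }
            for s in self.subjects
        ]
        return pd.DataFrame(rows).set_index("subject_id")

    def write(self, outdir: str | Path) -> None:
        """NIfTI images/masks plus the cohort CSV, one file set per subject."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s in self.subjects:
            if s.image is not None:
                save_nifti(outdir / f"{s.subject_id}_image.nii.gz",
                           s.image.data, s.image.spacing)
            if s.mask is not None:
                save_nifti(outdir / f"{s.subject_id}_mask.nii.gz",
                           s.mask.data.astype(np.uint8), s.mask.spacing)
            if s.mask_perturbed is not None:
                save_nifti(outdir / f"{s.subject_id}_mask_repeat.nii.gz",
                           s.mask_perturbed.data.astype(np.uint8),
                           s.mask_perturbed.spacing)
        self.table.to_csv(outdir / "cohort.csv")


_TSTAGE_PROBS = (0.07, 0.32, 0.20, 0.41)  # typical resected-RPS T-stage mix
_P_CYSTIC = {1: 0.76, 0: 0.45}            # cystic/necrosis rate by phenotype


def _phantom_spec_for(template: PhenotypeTemplate, grid_shape, rng, seed) -> PhantomSpec:
    v = template.n_habitats
    frags = tuple(
        int(f) for f in rng.integers(template.fragments_low,
                                     template.fragments_high + 1, size=v)
    )
    fracs = rng.dirichlet(np.full(v, template.dirichlet_alpha))
    # keep habitats at realizable, non-sliver sizes
    fracs = np.clip(fracs, 0.10, 0.60)
    fracs = tuple(float(f) for f in fracs / fracs.sum())
    textures = tuple(
        TextureParams(mean=40.0 + template.mean_spread * i,
                      sd=template.noise_sd,
                      corr_length=template.corr_length)
        for i in range(v)
    )
    return PhantomSpec(
        grid_shape=grid_shape, n_habitats=v, habitat_fragments=frags,
        area_fractions=fracs, texture_params=textures, seed=seed,
    )


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort per the spec (see class docstring)."""
    ss = np.random.SeedSequence(spec.seed)
    subjects: list[SyntheticSubject] = []
    children = ss.spawn(spec.n_subjects)
    for i in range(spec.n_subjects):
        sub_ss = children[i]
        rng = np.random.default_rng(sub_ss)
        phenotype = int(rng.random() < spec.prevalence)
        template = spec.high_template if phenotype else spec.low_template
        phantom_seed = int(rng.integers(0, 2**31 - 1))
        pspec = _phantom_spec_for(template, spec.grid_shape, rng, phantom_seed)
        batch = int(rng.integers(0, spec.n_batches))
        if spec.with_images:
            image, mask, tlm = generate_texture_phantom(pspec)
            img = image.data * spec.batch_scale_shifts[batch] + spec.batch_loc_shifts[batch]
            image = ImageVolume(img, image.spacing)
            mask_p = perturb_mask(
                mask, spec.mask_perturb_magnitude,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        else:
            # imageless subjects carry the analytic ground-truth ITH (the
            # equal-split closed form) instead of a realized partition,
            # which keeps survival-only cohorts cheap at large n
            image, mask, mask_p, tlm = None, None, None, None
        true_ith = (
            tlm.true_ith() if tlm is not None
            else true_ith_closed_form(pspec.area_fractions, pspec.habitat_fragments)
        )

        age = float(rng.normal(58.0, 11.0))
        sex = int(rng.random() < 0.5)
        t_stage = int(rng.choice([1, 2, 3, 4], p=_TSTAGE_PROBS))
        cystic = int(rng.random() < _P_CYSTIC[phenotype])

        eta = (
            spec.beta_ith * true_ith
            + spec.beta_cystic * cystic
            + spec.beta_tstage * t_stage
        )
        lam = spec.baseline_hazard * np.exp(eta)
        t_event = float(rng.exponential(1.0 / lam))
        dropout = float(rng.uniform(0.0, 2.0 * spec.horizon))
        c_time = min(dropout, spec.horizon)
        event = int(t_event <= c_time)
        time = min(t_event, c_time)
        subjects.append(
            SyntheticSubject(
                subject_id=f"S{i:04d}",
                batch=batch,
                phenotype=phenotype,
                image=image,
                mask=mask,
                mask_perturbed=mask_p,
                true_labels=tlm,
                true_ith=true_ith,
                age=age,
                sex=sex,
                t_stage=t_stage,
                cystic_necrosis=cystic,
                time_months=float(max(time, 1e-6)),
                event=event,
                latent_event_time=t_event,
            )
        )
    return SyntheticCohort(spec=spec, subjects=subjects)


def true_ith_closed_form(
    area_fractions: Sequence[float], fragments: Sequence[int]
) -> float:
    """Ground-truth ITH implied by equal-split fragments.

    With habitat ``i`` occupying fraction ``f_i`` of the tumor in ``m_i``
    equally sized connected pieces, the largest piece has area
    ``f_i * S / m_i`` and the score reduces to ``1 - sum_i f_i / m_i**2``.
    """
    return 1.0 - sum(f / m**2 for f, m in zip(area_fractions, fragments))


def expected_event_fraction(spec: CohortSpec, n_mc: int = 200_000,
                            seed: int = 12345) -> float:
    """Analytic event probability, averaged over the covariate distribution.

    Conditional on the subject's hazard rate ``lam`` the event probability
    has closed form under dropout ~ U(0, 2*horizon) capped at the horizon:
    ``P = 1/2 - (1 - e^(-lam*h)) / (2*lam*h) + (1 - e^(-lam*h)) / 2``.
    The covariate expectation is taken by Monte Carlo over the generator's
    own covariate distribution (deterministic given ``seed``).
    """
    rng = np.random.default_rng(seed)
    h = spec.horizon
    phen = rng.random(n_mc) < spec.prevalence
    # true ITH distribution: approximate by sampling template fragments/fractions
    ith = np.empty(n_mc)
    for z, template in ((0, spec.low_template), (1, spec.high_template)):
        idx = np.flatnonzero(phen == bool(z))
        v = template.n_habitats
        frags = rng.integers(template.fragments_low, template.fragments_high + 1,
                             size=(len(idx), v))
        fracs = rng.dirichlet(np.full(v, template.dirichlet_alpha), size=len(idx))
        ith[idx] = 1.0 - np.sum(fracs / frags**2, axis=1)
    cystic = np.where(
        phen, rng.random(n_mc) < _P_CYSTIC[1], rng.random(n_mc) < _P_CYSTIC[0]
    ).astype(float)
    t_stage = rng.choice([1, 2, 3, 4], p=_TSTAGE_PROBS, size=n_mc).astype(float)
    lam = spec.baseline_hazard * np.exp(
        spec.beta_ith * ith + spec.beta_cystic * cystic + spec.beta_tstage * t_stage
    )
    lh = lam * h
    p = 0.5 - (1.0 - np.exp(-lh)) / (2.0 * lh) + (1.0 - np.exp(-lh)) / 2.0
    return float(p.mean())
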