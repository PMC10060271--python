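"""Synthetic organoid plate simulator with known ground truth.

Simulates per-well organoid populations over a time-lapse — exponential
area growth with a density-dependent slowdown, fusion of touching
organoids, and Hill-type drug effects (cytostatic growth inhibition or
cytotoxic killing) — and renders paired brightfield / nuclear-blue /
death-green channels plus a labeled truth mask per frame.

Geometry is a flat 2-D projection: each organoid is a disk (solid) or an
annulus with a bright lumen (cystic). Positions are static; organoids do
not migrate, which matches the near-static phenomenology of embedded
organoid cultures. Wells belonging to one drug titration share the same
initial population (a paired design) so that differences across the
titration isolate the dose effect.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DrugSpec, PlateMap, SimulationConfig, ValidationError


@dataclass(frozen=True)
class OrganoidState:
    """Ground-truth state of one organoid at one frame."""

    organoid_id: int
    frame: int
    center_px: tuple[float, float]  # (row, col), 0-based, origin top-left
    area_um2: float
    morphology: str  # solid | cystic
    alive_fraction: float
    parent_ids: tuple[int, ...] = ()  # non-empty only at a fusion frame

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValidationError("area_um2: must be > 0")
        if not 0.0 <= self.alive_fraction <= 1.0:
            raise ValidationError("alive_fraction: must lie in [0, 1]")


@dataclass
class WellImageSet:
    """Multi-channel time-lapse stack for one well with physical scale."""

    well_id: str
    times_h: list[float]
    bf: np.ndarray  # (T, H, W) brightfield
    blue: np.ndarray | None  # nuclear channel
    green: np.ndarray | None  # cell-death channel
    um_per_px: float

    def __post_init__(self) -> None:
        for name, ch in (("blue", self.blue), ("green", self.green)):
            if ch is not None and ch.shape != self.bf.shape:
                raise ValidationError(f"{name}: channel shape {ch.shape} != bf {self.bf.shape}")
        t = np.asarray(self.times_h, dtype=float)
        if len(t) != self.bf.shape[0]:
            raise ValidationError("times_h: length must match number of frames")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("times_h: frame times must be strictly increasing")
        if self.um_per_px <= 0:
            raise ValidationError("um_per_px: must be > 0")

    @property
    def n_frames(self) -> int:
        return self.bf.shape[0]


@dataclass
class PlateTruth:
    """Simulator ground truth: per-organoid states and per-well expectations.

    ``states``: one row per (well, frame, organoid) with the OrganoidState
    fields. ``per_well_expected``: per (well, frame) the true count, mean
    area, total area, dead area and viable area (µm²).
    """

    states: pd.DataFrame
    per_well_expected: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)

    def well_states(self, well_id: str, frame: int) -> list[OrganoidState]:
        sub = self.states[(self.states.well_id == well_id) & (self.states.frame == frame)]
        out = []
        for _, r in sub.iterrows():
            out.append(
                OrganoidState(
                    organoid_id=int(r.organoid_id),
                    frame=int(r.frame),
                    center_px=(float(r.center_row), float(r.center_col)),
                    area_um2=float(r.area_um2),
                    morphology=str(r.morphology),
                    alive_fraction=float(r.alive_fraction),
                    parent_ids=tuple(int(p) for p in str(r.parent_ids).split(";") if p),
                )
            )
        return out


def _hill(conc: float, ec50: float, hill: float) -> float:
    """Fractional effect E(c) = c^h / (c^h + EC50^h)."""
    ch = conc**hill
    return ch / (ch + ec50**hill)


def _sub_rng(seed: int, *tokens) -> np.random.Generator:
    """Deterministic child RNG from the master seed and string/int tokens."""
    key = "|".join(str(t) for t in tokens)
    return np.random.default_rng([seed, zlib.crc32(key.encode())])


def _radius_px(area_um2: float, um_per_px: float) -> float:
    return float(np.sqrt(area_um2 / np.pi) / um_per_px)


@dataclass
class _Organoid:
    oid: int
    row: float
    col: float
    area: float  # µm²
    morphology: str
    alive: float = 1.0


def _place_organoids(cfg: SimulationConfig, rng: np.random.Generator) -> list[_Organoid]:
    """Rejection-sample non-overlapping initial positions within a margin.

    The edge margin leaves headroom for growth (radius doubles when area
    quadruples) so organoids stay inside the imaged field, matching
    whole-well imaging where truncation at the border is rare.
    """
    h, w = cfg.image_size_px
    orgs: list[_Organoid] = []
    sigma = np.sqrt(np.log(1 + cfg.init_area_cv**2))
    headroom = 2.0
    for i in range(cfg.seeding_density):
        area = cfg.init_area_um2 * float(rng.lognormal(0.0, sigma))
        r = _radius_px(area, cfg.um_per_px)
        morph = "solid" if rng.random() < cfg.morphology_mix else "cystic"
        placed = False
        for _ in range(200):
            row = rng.uniform(headroom * r + 2, h - headroom * r - 2)
            col = rng.uniform(headroom * r + 2, w - headroom * r - 2)
            gap_ok = all(
                np.hypot(row - o.row, col - o.col)
                > r + _radius_px(o.area, cfg.um_per_px) + 3
                for o in orgs
            )
            if gap_ok:
                orgs.append(_Organoid(i + 1, row, col, area, morph))
                placed = True
                break
        if not placed:
            raise ValidationError(
                "image_size_px: image too small to place requested organoids"
            )
    return orgs


def _drug_effect(cfg: SimulationConfig, role: str, drug: str | None, conc: float | None):
    """Return (growth_scale, kill_rate_h, alive_floor) for a well's treatment.

    Cytotoxic dosing is fractional kill: the dose determines which
    fraction of each organoid is killable (the floor of alive_fraction is
    ``1 − max_kill_fraction · E(c)``) and the floor is approached at rate
    ``kill_rate_h · E(c)``; surviving cells grow unaffected. Cytostatic
    dosing scales the growth rate by ``1 − E(c)`` without killing.
    """
    if role == "positive":
        return 1.0, cfg.control_kill_rate_h, 0.0  # maximal-kill control: E(c) = 1
    if role != "treated" or drug is None:
        return 1.0, 0.0, 0.0
    spec = next((s for s in cfg.drug_panel if s.name == drug), None)
    if spec is None:
        raise ValidationError(f"drug: {drug!r} not in simulation drug_panel")
    e = _hill(float(conc), spec.ec50_true, spec.hill_true)
    if spec.mode == "cytostatic":
        return 1.0 - e, 0.0, 1.0
    return 1.0, cfg.kill_rate_h * e, 1.0 - spec.max_kill_fraction * e


def _merge_overlapping(
    orgs: list[_Organoid], um_per_px: float
) -> tuple[list[_Organoid], dict[int, tuple[int, ...]]]:
    """Union-find merge of organoids whose disks touch; lowest id survives."""
    n = len(orgs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    radii = [_radius_px(o.area, um_per_px) for o in orgs]
    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(orgs[i].row - orgs[j].row, orgs[i].col - orgs[j].col) <= (
                radii[i] + radii[j]
            ):
                parent[find(i)] = find(j)

    groups: dict[int, list[_Organoid]] = {}
    for i, o in enumerate(orgs):
        groups.setdefault(find(i), []).append(o)

    merged: list[_Organoid] = []
    parents_of: dict[int, tuple[int, ...]] = {}
    for members in groups.values():
        if len(members) == 1:
            merged.append(members[0])
            continue
        area = sum(o.area for o in members)
        row = sum(o.row * o.area for o in members) / area
        col = sum(o.col * o.area for o in members) / area
        alive = sum(o.alive * o.area for o in members) / area
        biggest = max(members, key=lambda o: o.area)
        oid = min(o.oid for o in members)
        merged.append(_Organoid(oid, row, col, area, biggest.morphology, alive))
        parents_of[oid] = tuple(sorted(o.oid for o in members))
    merged.sort(key=lambda o: o.oid)
    return merged, parents_of


def simulate_plate(config: SimulationConfig, plate_map: PlateMap) -> PlateTruth:
    """Run the population simulation for every well in the plate map.

    Returns a :class:`PlateTruth` whose per-well table is the exact
    aggregation of the per-organoid states (conservation holds by
    construction). Deterministic given ``config.seed``.
    """
    plate_map.validate_for_format(config.plate_format)
    roles = set(plate_map.table["role"])
    if config.drug_panel and ("treated" in roles):
        if "vehicle" not in roles or "positive" not in roles:
            raise ValidationError(
                "plate map with treated wells requires >=1 vehicle and >=1 positive control"
            )

    state_rows: list[dict] = []
    well_rows: list[dict] = []

    for wrow in plate_map.rows():
        well = wrow.well_id
        role = wrow.role
        drug = wrow.drug if isinstance(wrow.drug, str) else None
        conc = wrow.concentration
        if role == "empty":
            for t in range(config.n_timepoints):
                well_rows.append(
                    {"well_id": well, "frame": t, "time_h": config.times_h[t],
                     "count": 0, "mean_area_um2": 0.0, "total_area_um2": 0.0,
                     "dead_area_um2": 0.0, "viable_area_um2": 0.0}
                )
            continue

        # Matched titrations: all wells of one (drug, replicate) share an
        # initial population; controls are seeded per role+replicate.
        init_key = (drug, int(wrow.replicate)) if drug else (role, int(wrow.replicate))
        rng = _sub_rng(config.seed, "init", *init_key)
        orgs = _place_organoids(config, rng)
        growth_scale, kill_rate, floor = _drug_effect(config, role, drug, conc)
        pending_parents: dict[int, tuple[int, ...]] = {}

        for t in range(config.n_timepoints):
            total = sum(o.area for o in orgs)
            dead = sum(o.area * (1.0 - o.alive) for o in orgs)
            n = len(orgs)
            for o in orgs:
                state_rows.append(
                    {"well_id": well, "frame": t, "time_h": config.times_h[t],
                     "organoid_id": o.oid, "center_row": o.row, "center_col": o.col,
                     "area_um2": o.area, "morphology": o.morphology,
                     "alive_fraction": o.alive,
                     "parent_ids": ";".join(str(p) for p in pending_parents.get(o.oid, ()))}
                )
            well_rows.append(
                {"well_id": well, "frame": t, "time_h": config.times_h[t],
                 "count": n, "mean_area_um2": total / n if n else 0.0,
                 "total_area_um2": total, "dead_area_um2": dead,
                 "viable_area_um2": total - dead}
            )
            if t == config.n_timepoints - 1:
                break
            # advance by dt: killing toward the dose-dependent floor, then
            # growth of the surviving compartment (dead area is frozen)
            g = config.growth_rate_h * growth_scale
            if len(orgs) > config.density_slowdown_threshold:
                g *= config.density_slowdown_factor
            grow = float(np.exp(g * config.dt_h))
            for o in orgs:
                if kill_rate > 0 and o.alive > floor:
                    o.alive = floor + (o.alive - floor) * float(
                        np.exp(-kill_rate * config.dt_h)
                    )
                new_area = o.area * (1.0 - o.alive) + o.area * o.alive * grow
                o.alive = o.area * o.alive * grow / new_area
                o.area = new_area
            orgs, pending_parents = _merge_overlapping(orgs, config.um_per_px)

    states = pd.DataFrame.from_records(
        state_rows,
        columns=["well_id", "frame", "time_h", "organoid_id", "center_row",
                 "center_col", "area_um2", "morphology", "alive_fraction", "parent_ids"],
    )
    per_well = pd.DataFrame.from_records(well_rows)
    return PlateTruth(states=states, per_well_expected=per_well, config=config)


# ---------------------------------------------------------------------------
# Rendering


def _disk_mask(h: int, w: int, row: float, col: float, radius: float) -> np.ndarray:
    rr, cc = np.ogrid[:h, :w]
    return (rr - row) ** 2 + (cc - col) ** 2 <= radius**2


def render_well(
    states: list[OrganoidState],
    config: SimulationConfig,
    well_id: str = "A01",
    frame: int | None = None,
    artifacts: bool = True,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Render one (well, frame) to BF/blue/green rasters plus a truth mask.

    Brightfield: solid organoids are dark textured disks, cystic ones dark
    annuli with a bright lumen. Blue: nuclear signal over the full object
    (solid) or the rim only (cystic). Green: signal over the dead fraction,
    drawn as a concentric core growing from the interior. Air bubbles
    (bright rings) and debris (small dark specks) are added per the
    configured rates and are excluded from the truth mask.

    Returns ``(channels, labels)`` where ``channels`` maps "bf"/"blue"/
    "green" to float rasters in [0, 1] and ``labels`` is a uint16 raster
    with 0 background and each organoid's id elsewhere.
    """
    if frame is None:
        frame = states[0].frame if states else 0
    frames = {s.frame for s in states}
    if len(frames) > 1:
        raise ValidationError("states: must all belong to a single frame")

    h, w = config.image_size_px
    labels = np.zeros((h, w), dtype=np.uint16)
    bf = np.full((h, w), 0.55)
    blue = np.full((h, w), 0.05)
    green = np.full((h, w), 0.05)
    rng = _sub_rng(config.seed, "render", well_id, frame)

    for s in states:
        r = _radius_px(s.area_um2, config.um_per_px)
        row, col = s.center_px
        if r >= min(h, w) / 2:
            raise ValidationError("image_size_px: image too small for organoid radius")
        disk = _disk_mask(h, w, row, col, r)
        labels[disk] = s.organoid_id
        texture = rng.normal(0.0, 0.04, size=(h, w))
        if s.morphology == "solid":
            bf[disk] = 0.30 + texture[disk]
            blue[disk] = 0.80
        else:
            rim = disk & ~_disk_mask(h, w, row, col, max(r * 0.78, r - 4.0))
            lumen = disk & ~rim
            bf[rim] = 0.28 + texture[rim]
            bf[lumen] = 0.72
            blue[rim] = 0.80
        dead = 1.0 - s.alive_fraction
        if dead > 1e-9:
            core = _disk_mask(h, w, row, col, r * np.sqrt(dead))
            core &= disk
            green[core] = 0.75

    if artifacts:
        organoid_any = labels > 0
        n_bub = rng.poisson(config.bubble_rate)
        for _ in range(n_bub):
            rb = rng.uniform(10, 25)
            for _ in range(30):
                brow, bcol = rng.uniform(0, h), rng.uniform(0, w)
                ring = _disk_mask(h, w, brow, bcol, rb) & ~_disk_mask(
                    h, w, brow, bcol, rb - 2.5
                )
                if not (ring & organoid_any).any():
                    bf[ring] = 0.92
                    break
        n_deb = rng.poisson(config.debris_rate)
        for _ in range(n_deb):
            rd = rng.uniform(1.0, 2.5)
            for _ in range(30):
                drow, dcol = rng.uniform(0, h), rng.uniform(0, w)
                speck = _disk_mask(h, w, drow, dcol, rd)
                if not (speck & organoid_any).any():
                    bf[speck] = 0.10
                    break

    # smooth multiplicative illumination gradient + Gaussian read noise
    gy = rng.uniform(-1, 1) * config.illumination_gradient
    gx = rng.uniform(-1, 1) * config.illumination_gradient
    plane = 1.0 + gy * (np.arange(h)[:, None] / h - 0.5) + gx * (np.arange(w)[None, :] / w - 0.5)
    channels = {}
    for name, img in (("bf", bf), ("blue", blue), ("green", green)):
        noisy = img * plane + rng.normal(0.0, config.read_noise_sd, size=(h, w))
        channels[name] = np.clip(noisy, 0.0, 1.0)
    return channels, labels


def render_well_stack(
    truth: PlateTruth, well_id: str, artifacts: bool = True
) -> tuple[WellImageSet, list[np.ndarray]]:
    """Render every frame of one well into a WellImageSet plus truth masks."""
    cfg = truth.config
    bf, blue, green, masks = [], [], [], []
    for t in range(cfg.n_timepoints):
        ch, lab = render_well(
            truth.well_states(well_id, t), cfg, well_id=well_id, frame=t,
            artifacts=artifacts,
        )
        bf.append(ch["bf"])
        blue.append(ch["blue"])
        green.append(ch["green"])
        masks.append(lab)
    images = WellImageSet(
        well_id=well_id,
        times_h=cfg.times_h,
        bf=np.stack(bf),
        blue=np.stack(blue),
        green=np.stack(green),
        um_per_px=cfg.um_per_px,
    )
    return images, masks
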