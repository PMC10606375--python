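"""Discretised skin barrier: brick-and-mortar stratum corneum over viable
epidermis and dermis.

The stratum corneum (SC) is a 2-D unit cell of corneocyte "bricks" embedded
in continuous lipid "mortar": alternating lipid and corneocyte strata, with a
thin vertical lipid channel crossing each corneocyte stratum.  Successive
strata stagger the channel laterally by ``brick_offset`` of the unit-cell
period, and the lateral boundary wraps periodically.  Viable epidermis (VE)
and dermis (DM) are homogeneous diffusive slabs discretised in 1-D.

Transport between cells uses the generic interface-flux law; the
lipid <-> corneocyte interfaces carry direction-specific permeabilities
(horizontal for lateral links, vertical for depth links) as the calibrated
skin parameters prescribe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import units
from .core import (DomainError, _check_positive, geometric_widths,
                   series_permeability)
from .network import FluxNetwork

LIPID, CORNEOCYTE = "lipid", "corneocyte"


@dataclass(frozen=True)
class SkinGeometry:
    sc_thickness: float = 14.075 * units.UM
    corneocyte_diameter: float = 40 * units.UM
    corneocyte_thickness: float = 0.8 * units.UM
    lipid_thickness: float = 0.075 * units.UM
    ve_thickness: float = 56 * units.UM
    dermis_thickness: float = 1.2 * units.MM
    brick_offset: float = 0.5
    channel_width: float | None = None   # lateral lipid channel; default = lipid_thickness

    def __post_init__(self) -> None:
        _check_positive(sc_thickness=self.sc_thickness,
                        corneocyte_diameter=self.corneocyte_diameter,
                        corneocyte_thickness=self.corneocyte_thickness,
                        lipid_thickness=self.lipid_thickness,
                        ve_thickness=self.ve_thickness,
                        dermis_thickness=self.dermis_thickness)
        if not (0.0 <= self.brick_offset < 1.0):
            raise DomainError("brick_offset must lie in [0, 1)")

    @property
    def channel(self) -> float:
        return self.channel_width if self.channel_width is not None else self.lipid_thickness

    def with_specimen_thickness(self, specimen: float) -> "SkinGeometry":
        """Rescale the dermis so the full stack matches a dermatomed specimen."""
        dm = specimen - self.sc_thickness - self.ve_thickness
        if dm <= 0:
            raise DomainError("specimen thinner than SC + viable epidermis")
        return SkinGeometry(self.sc_thickness, self.corneocyte_diameter,
                            self.corneocyte_thickness, self.lipid_thickness,
                            self.ve_thickness, dm, self.brick_offset,
                            self.channel_width)


@dataclass(frozen=True)
class SkinTransport:
    """Transport parameters of the layered skin model.

    The six leading fields mirror the calibrated skin-parameter table; the
    remaining fields are the unprinted model constants, exposed with neutral
    partition coefficients and literature-scale intraphase diffusivities.
    ``perm_lc_*`` of None falls back to the two-film series formula (useful
    for homogeneous-limit tests).
    """
    kp_lipid_vehicle: float = 18.8
    perm_lc_horizontal: float | None = 1.04e-10   # m/s
    perm_lc_vertical: float | None = 5.2e-9       # m/s
    diff_ve: float = 1.1e-9                       # m^2/s
    diff_dermis: float = 1.1e-9                   # m^2/s
    perm_dermis_receptor: float = 3.5e-7          # m/s
    diff_lipid: float = 1e-13
    diff_corneocyte: float = 1e-13
    kp_cor_lipid: float = 1.0                     # C_cor/C_lip at equilibrium
    kp_ve_lipid: float = 1.0                      # C_ve/C_lip
    kp_dm_ve: float = 1.0
    kp_receptor_dm: float = 1.0

    def __post_init__(self) -> None:
        _check_positive(kp_lipid_vehicle=self.kp_lipid_vehicle,
                        diff_ve=self.diff_ve, diff_dermis=self.diff_dermis,
                        perm_dermis_receptor=self.perm_dermis_receptor,
                        diff_lipid=self.diff_lipid,
                        diff_corneocyte=self.diff_corneocyte,
                        kp_cor_lipid=self.kp_cor_lipid,
                        kp_ve_lipid=self.kp_ve_lipid, kp_dm_ve=self.kp_dm_ve,
                        kp_receptor_dm=self.kp_receptor_dm)
        for name in ("perm_lc_horizontal", "perm_lc_vertical"):
            v = getattr(self, name)
            if v is not None:
                _check_positive(**{name: v})

    def diffusivity(self, phase: str) -> float:
        return self.diff_lipid if phase == LIPID else self.diff_corneocyte


@dataclass
class SCGrid:
    """2-D brick-and-mortar unit cell of the stratum corneum."""
    geometry: SkinGeometry
    n_corneocyte_layers: int
    n_lipid_layers: int
    row_thickness: np.ndarray      # per stratum, top (vehicle side) first
    row_phase: list[str]           # stratum bulk phase
    col_widths: np.ndarray         # lateral partition of the unit cell
    is_lipid: np.ndarray           # (n_rows, n_cols) phase map
    period: float                  # lateral unit-cell period Lx

    @property
    def n_rows(self) -> int:
        return len(self.row_thickness)

    @property
    def n_cols(self) -> int:
        return len(self.col_widths)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_index(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def volumes(self, contact_area: float) -> np.ndarray:
        frac = self.col_widths / self.period
        v = np.outer(self.row_thickness, frac) * contact_area
        return v.ravel()


def build_sc_grid(geometry: SkinGeometry, lateral_subcells: int = 2) -> SCGrid:
    """Construct the brick-and-mortar SC grid from the layer geometry.

    The stratum count must satisfy n*t_cor + (n+1)*t_lip = sc_thickness to
    within 1 nm; for the reference geometry (14.075, 0.8, 0.075 um) this gives
    16 corneocyte and 17 lipid strata.
    """
    g = geometry
    n = (g.sc_thickness - g.lipid_thickness) / (g.corneocyte_thickness + g.lipid_thickness)
    n_cor = int(round(n))
    residual = g.sc_thickness - (n_cor * g.corneocyte_thickness
                                 + (n_cor + 1) * g.lipid_thickness)
    if n_cor < 1 or abs(residual) > 1e-9:
        raise DomainError(
            "SC thickness is not commensurate with the stratum thicknesses: "
            f"residual {residual:.3e} m for n = {n_cor} corneocyte layers")
    n_lip = n_cor + 1

    # lateral partition: one channel-width column at every distinct stagger
    # position, corneocyte spans between them subdivided laterally
    w_ch = g.channel
    lx = g.corneocyte_diameter + w_ch
    positions = sorted({round((k * g.brick_offset) % 1.0, 9) for k in range(n_cor)})
    starts = [p * lx for p in positions]
    for a, b in zip(starts, starts[1:] + [starts[0] + lx]):
        if b - a < w_ch * (1 + 1e-9):
            raise DomainError("brick_offset places lateral channels closer than "
                              "one channel width; choose a coarser offset")
    col_widths: list[float] = []
    col_kind: list[tuple[str, float | None]] = []  # ("channel", pos) / ("span", None)
    for i, s in enumerate(starts):
        col_widths.append(w_ch)
        col_kind.append(("channel", positions[i]))
        nxt = starts[(i + 1) % len(starts)] + (lx if i == len(starts) - 1 else 0.0)
        gap = nxt - (s + w_ch)
        if gap > 0:
            for _ in range(max(1, lateral_subcells)):
                col_widths.append(gap / max(1, lateral_subcells))
                col_kind.append(("span", None))

    rows_t, rows_p = [], []
    for k in range(n_cor):
        rows_t += [g.lipid_thickness, g.corneocyte_thickness]
        rows_p += [LIPID, CORNEOCYTE]
    rows_t.append(g.lipid_thickness)
    rows_p.append(LIPID)

    n_rows, n_cols = len(rows_t), len(col_widths)
    is_lipid = np.zeros((n_rows, n_cols), dtype=bool)
    cor_stratum = 0
    for r, phase in enumerate(rows_p):
        if phase == LIPID:
            is_lipid[r, :] = True
        else:
            own = round((cor_stratum * g.brick_offset) % 1.0, 9)
            for c, (kind, pos) in enumerate(col_kind):
                is_lipid[r, c] = (kind == "channel" and pos == own)
            cor_stratum += 1

    return SCGrid(geometry=g, n_corneocyte_layers=n_cor, n_lipid_layers=n_lip,
                  row_thickness=np.asarray(rows_t), row_phase=rows_p,
                  col_widths=np.asarray(col_widths), is_lipid=is_lipid, period=lx)


@dataclass
class SkinStack:
    """Full barrier: SC grid cells, then VE cells, then dermis cells.

    Local indices: SC cells first (row-major), then VE top-to-bottom, then
    dermis; the receptor is *not* part of the stack.
    """
    geometry: SkinGeometry
    transport: SkinTransport
    grid: SCGrid
    contact_area: float
    ve_widths: np.ndarray
    dm_widths: np.ndarray

    def __post_init__(self) -> None:
        self.n_sc = self.grid.n_cells
        self.n_ve = len(self.ve_widths)
        self.n_dm = len(self.dm_widths)

    @property
    def n_cells(self) -> int:
        return self.n_sc + self.n_ve + self.n_dm

    @property
    def total_thickness(self) -> float:
        g = self.geometry
        return g.sc_thickness + g.ve_thickness + g.dermis_thickness

    def state_volumes(self) -> np.ndarray:
        return np.concatenate([self.grid.volumes(self.contact_area),
                               self.ve_widths * self.contact_area,
                               self.dm_widths * self.contact_area])

    def state_labels(self) -> list[str]:
        labels = []
        for r in range(self.grid.n_rows):
            for c in range(self.grid.n_cols):
                ph = "lip" if self.grid.is_lipid[r, c] else "cor"
                labels.append(f"sc_{ph}[{r},{c}]")
        labels += [f"ve[{i}]" for i in range(self.n_ve)]
        labels += [f"dm[{i}]" for i in range(self.n_dm)]
        return labels

    def groups(self) -> dict[str, np.ndarray]:
        lip_mask = self.grid.is_lipid.ravel()
        sc_idx = np.arange(self.n_sc)
        ve_idx = self.n_sc + np.arange(self.n_ve)
        dm_idx = self.n_sc + self.n_ve + np.arange(self.n_dm)
        return {"sc_lipid": sc_idx[lip_mask], "sc_corneocyte": sc_idx[~lip_mask],
                "ve": ve_idx, "dermis": dm_idx}

    # boundary bookkeeping used by the Franz-cell assembler
    def top_cells(self) -> list[tuple[int, float]]:
        """(index, area) of the vehicle-facing top lipid row."""
        frac = self.grid.col_widths / self.grid.period
        return [(self.grid.cell_index(0, c), self.contact_area * frac[c])
                for c in range(self.grid.n_cols)]

    @property
    def dm_bottom(self) -> int:
        return self.n_cells - 1


def build_skin_stack(geometry: SkinGeometry, transport: SkinTransport,
                     contact_area: float, lateral_subcells: int = 2,
                     ve_cells: int = 10, dm_cells: int = 20,
                     grid_ratio: float = 1.3) -> SkinStack:
    grid = build_sc_grid(geometry, lateral_subcells)
    ve_w = np.asarray(geometric_widths(geometry.ve_thickness, ve_cells,
                                       grid_ratio, refine="both"))
    dm_w = np.asarray(geometric_widths(geometry.dermis_thickness, dm_cells,
                                       grid_ratio, refine="both"))
    return SkinStack(geometry=geometry, transport=transport, grid=grid,
                     contact_area=contact_area, ve_widths=ve_w, dm_widths=dm_w)


def _mixed_link(idx_a: int, idx_b: int, a_is_lipid: bool, perm: float | None,
                t: SkinTransport, d_half_a: float, d_half_b: float,
                sa: float) -> tuple[int, int, float, float, float]:
    """Lipid<->corneocyte link, canonically oriented lipid -> corneocyte."""
    lip, cor = (idx_a, idx_b) if a_is_lipid else (idx_b, idx_a)
    dh_l, dh_c = (d_half_a, d_half_b) if a_is_lipid else (d_half_b, d_half_a)
    if perm is not None:
        p = perm
    else:
        p = series_permeability(dh_l, t.diff_lipid, dh_c, t.diff_corneocyte,
                                t.kp_cor_lipid)
    return (lip, cor, p, sa, t.kp_cor_lipid)


def assemble_flux_network(stack: SkinStack, transport: SkinTransport,
                          contact_area: float) -> list[tuple[int, int, float, float, float]]:
    """All intra-stack links as (ia, ib, P, SA, kp) tuples (local indices).

    Depth-direction lipid/corneocyte interfaces carry the vertical
    permeability, lateral ones the horizontal permeability; same-phase links
    use the two-film series formula with the phase diffusivities.  The SC
    wraps periodically in the lateral direction.
    """
    if contact_area <= 0:
        raise DomainError("contact_area must be positive")
    g, t = stack.grid, transport
    links: list[tuple[int, int, float, float, float]] = []
    frac = g.col_widths / g.period

    # SC vertical (depth-direction) links
    for r in range(g.n_rows - 1):
        t0, t1 = g.row_thickness[r], g.row_thickness[r + 1]
        for c in range(g.n_cols):
            ia, ib = g.cell_index(r, c), g.cell_index(r + 1, c)
            sa = contact_area * frac[c]
            la, lb = g.is_lipid[r, c], g.is_lipid[r + 1, c]
            if la != lb:
                links.append(_mixed_link(ia, ib, la, t.perm_lc_vertical, t,
                                         t0 / 2, t1 / 2, sa))
            else:
                d = t.diffusivity(LIPID if la else CORNEOCYTE)
                links.append((ia, ib, 2 * d / (t0 + t1), sa, 1.0))

    # SC horizontal (lateral) links, periodic wrap
    for r in range(g.n_rows):
        sa = contact_area * g.row_thickness[r] / g.period
        for c in range(g.n_cols):
            c2 = (c + 1) % g.n_cols
            ia, ib = g.cell_index(r, c), g.cell_index(r, c2)
            w0, w1 = g.col_widths[c], g.col_widths[c2]
            la, lb = g.is_lipid[r, c], g.is_lipid[r, c2]
            if la != lb:
                links.append(_mixed_link(ia, ib, la, t.perm_lc_horizontal, t,
                                         w0 / 2, w1 / 2, sa))
            else:
                d = t.diffusivity(LIPID if la else CORNEOCYTE)
                links.append((ia, ib, 2 * d / (w0 + w1), sa, 1.0))

    # SC bottom lipid row -> first VE cell
    ve0 = stack.n_sc
    t_bot = g.row_thickness[-1]
    for c in range(g.n_cols):
        ia = g.cell_index(g.n_rows - 1, c)
        p = series_permeability(t_bot / 2, t.diff_lipid,
                                stack.ve_widths[0] / 2, t.diff_ve, t.kp_ve_lipid)
        links.append((ia, ve0, p, contact_area * frac[c], t.kp_ve_lipid))

    # VE internal
    for i in range(stack.n_ve - 1):
        w0, w1 = stack.ve_widths[i], stack.ve_widths[i + 1]
        links.append((ve0 + i, ve0 + i + 1, 2 * t.diff_ve / (w0 + w1),
                      contact_area, 1.0))

    # VE -> dermis
    dm0 = stack.n_sc + stack.n_ve
    p = series_permeability(stack.ve_widths[-1] / 2, t.diff_ve,
                            stack.dm_widths[0] / 2, t.diff_dermis, t.kp_dm_ve)
    links.append((ve0 + stack.n_ve - 1, dm0, p, contact_area, t.kp_dm_ve))

    # dermis internal  (dermis -> receptor is the Franz assembler's job)
    for i in range(stack.n_dm - 1):
        w0, w1 = stack.dm_widths[i], stack.dm_widths[i + 1]
        links.append((dm0 + i, dm0 + i + 1, 2 * t.diff_dermis / (w0 + w1),
                      contact_area, 1.0))
    return links


def homogenized_sc_resistance(stack: SkinStack, transport: SkinTransport) -> float:
    """Effective SC permeability (m/s) from the steady linear system.

    A unit concentration drop is imposed across the SC between two virtual
    lipid-phase faces; the returned value is flux / (area * dC).  Diagnostic
    only - the transient simulation uses the full grid.
    """
    g, t = stack.grid, transport
    area = stack.contact_area
    n_sc = stack.n_sc
    top, bottom = n_sc, n_sc + 1
    vols = np.concatenate([stack.grid.volumes(area), [1.0, 1.0]])
    net = FluxNetwork(vols)
    for ia, ib, p, sa, kp in assemble_flux_network(stack, transport, area):
        if ia < n_sc and ib < n_sc:
            net.add_link(ia, ib, p, sa, kp)
    frac = g.col_widths / g.period
    for c in range(g.n_cols):
        sa = area * frac[c]
        net.add_link(top, g.cell_index(0, c),
                     2 * t.diff_lipid / g.row_thickness[0], sa, 1.0)
        net.add_link(g.cell_index(g.n_rows - 1, c), bottom,
                     2 * t.diff_lipid / g.row_thickness[-1], sa, 1.0)
    net.freeze()
    conc = net.steady_concentrations({top: 1.0, bottom: 0.0})
    flux_in = -net.node_net_flux(conc)[top]   # kg/s leaving the top face
    if flux_in <= 0:
        raise DomainError("no steady flux through the SC network; disconnected?")
    return flux_in / (area * 1.0)
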