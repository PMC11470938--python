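"""Bilateral HS–H2–bIPS–uLPTCrn rate network with gap-junction coupling.

A linear steady-state rate model of eight wide-field motion-sensitive
cells (HS, H2, bIPS, uLPTCrn in each hemisphere).  Each hemisphere's HS
cell receives opponent ipsilateral input (front-to-back excitation,
back-to-front suppression); H2 receives strong ipsilateral back-to-front
input plus a weak (0.1) contralateral front-to-back input; contralateral
chemical input to HS is zero — HS instead receives contralateral
back-to-front information electrically, through a gap junction with the
contralateral H2.  bIPS is an inhibitory interneuron driven by the
contralateral H2; uLPTCrn combines ipsilateral HS with disinhibition via
bIPS.  Gap junctions are ohmic: an edge of conductance g contributes the
graph-Laplacian term g(V_j − V_i) to each endpoint, conserving current.

Steady state solves  (I − W_chem + L_gap) · V = D · s  for the four
canonical optic-flow conditions (clockwise / counterclockwise rotation,
forward / backward translation).  Selectivity is summarised by the
Discrimination Index

    DI = (OF_translation − OF_rotation) / (|OF_translation| + |OF_rotation|)

where each OF term is the max−min response range over the corresponding
condition pair: DI = +1 for purely translation-selective cells, −1 for
purely rotation-selective ones.

Default weights are model assumptions chosen so that (i) the stated
settings hold (0.1 contralateral FtB→H2, 0 contralateral chem→HS), and
(ii) increasing gap conductance monotonically increases rotation
selectivity (lowers DI) in every cell — see docs/methods.md for the
closed-form analysis behind the choices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CELLS = ("HS_L", "H2_L", "bIPS_L", "uLPTCrn_L", "HS_R", "H2_R", "bIPS_R", "uLPTCrn_R")
CONDITIONS = ("clockwise", "counterclockwise", "forward_translation", "backward_translation")
# per-eye input channels driving the network
INPUTS = ("sL_FtB", "sL_BtF", "sR_FtB", "sR_BtF")

DEFAULT_WEIGHTS = {
    "hs_ipsi_ftb": 1.0,
    "hs_ipsi_btf": -1.0,  # opponent suppression
    "hs_contra": 0.0,  # stated setting: no contralateral chemical input to HS
    "h2_ipsi_btf": 2.2,  # keeps H2's fwd/bwd ordering fixed across g in [0, 1]
    "h2_contra_ftb": 0.1,  # stated setting
    "h2_to_bips": -0.5,  # inhibitory: bIPS is suppressed by contralateral H2
    "hs_to_ulptcrn": 1.0,
    "bips_to_ulptcrn": -1.0,  # inhibition; with h2_to_bips < 0 this disinhibits
}
DEFAULT_GAP_CONDUCTANCE = 0.5


class NetworkSolveError(RuntimeError):
    """Singular steady-state system or non-convergent rectified iteration."""


@dataclass
class NetworkConfig:
    w_chem: np.ndarray  # (8, 8), w_chem[i, j] = weight from cell j onto cell i
    drive: np.ndarray  # (8, 4), maps (sL_FtB, sL_BtF, sR_FtB, sR_BtF) to cells
    gap_edges: tuple[tuple[str, str], ...] = (("HS_L", "H2_R"), ("HS_R", "H2_L"))
    g: float = DEFAULT_GAP_CONDUCTANCE
    rectify: bool = False

    def __post_init__(self) -> None:
        self.w_chem = np.asarray(self.w_chem, dtype=float)
        self.drive = np.asarray(self.drive, dtype=float)
        if self.w_chem.shape != (8, 8) or self.drive.shape != (8, 4):
            raise ValueError("w_chem must be 8×8 and drive 8×4")
        if self.g < 0:
            raise ValueError("gap conductance must be non-negative")

    def to_json(self) -> str:
        return json.dumps(
            {
                "cells": CELLS,
                "w_chem": self.w_chem.tolist(),
                "drive": self.drive.tolist(),
                "gap_edges": self.gap_edges,
                "g": self.g,
                "rectify": self.rectify,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "NetworkConfig":
        d = json.loads(s)
        return cls(
            w_chem=np.array(d["w_chem"]),
            drive=np.array(d["drive"]),
            gap_edges=tuple(tuple(e) for e in d["gap_edges"]),
            g=d["g"],
            rectify=d.get("rectify", False),
        )


def _idx(cell: str) -> int:
    return CELLS.index(cell)


def default_config(g: float = DEFAULT_GAP_CONDUCTANCE, weights: dict | None = None,
                   rectify: bool = False) -> NetworkConfig:
    """Mirror-symmetric default network (weights documented above)."""
    wt = {**DEFAULT_WEIGHTS, **(weights or {})}
    W = np.zeros((8, 8))
    D = np.zeros((8, 4))
    for hemi, contra in (("L", "R"), ("R", "L")):
        ftb, btf = f"s{hemi}_FtB", f"s{hemi}_BtF"
        cftb = f"s{contra}_FtB"
        D[_idx(f"HS_{hemi}"), INPUTS.index(ftb)] = wt["hs_ipsi_ftb"]
        D[_idx(f"HS_{hemi}"), INPUTS.index(btf)] = wt["hs_ipsi_btf"]
        D[_idx(f"H2_{hemi}"), INPUTS.index(btf)] = wt["h2_ipsi_btf"]
        D[_idx(f"H2_{hemi}"), INPUTS.index(cftb)] = wt["h2_contra_ftb"]
        W[_idx(f"bIPS_{hemi}"), _idx(f"H2_{contra}")] = wt["h2_to_bips"]
        W[_idx(f"uLPTCrn_{hemi}"), _idx(f"HS_{hemi}")] = wt["hs_to_ulptcrn"]
        W[_idx(f"uLPTCrn_{hemi}"), _idx(f"bIPS_{hemi}")] = wt["bips_to_ulptcrn"]
    return NetworkConfig(w_chem=W, drive=D, g=g, rectify=rectify)


def condition_drives() -> dict[str, np.ndarray]:
    """Input vectors (sL_FtB, sL_BtF, sR_FtB, sR_BtF) for the 4 conditions.

    A clockwise rotation sweeps front-to-back across the left eye and
    back-to-front across the right; translation drives both eyes with the
    same motion class.  Each drive has total input mass 2.
    """
    return {
        "clockwise": np.array([1.0, 0.0, 0.0, 1.0]),
        "counterclockwise": np.array([0.0, 1.0, 1.0, 0.0]),
        "forward_translation": np.array([1.0, 0.0, 1.0, 0.0]),
        "backward_translation": np.array([0.0, 1.0, 0.0, 1.0]),
    }


def gap_laplacian(gap_edges, g: float, n: int = 8, index=None) -> np.ndarray:
    """Graph Laplacian of the gap-junction edges scaled by conductance g."""
    L = np.zeros((n, n))
    for a, b in gap_edges:
        i = _idx(a) if index is None else index(a)
        j = _idx(b) if index is None else index(b)
        L[i, i] += g
        L[j, j] += g
        L[i, j] -= g
        L[j, i] -= g
    return L


def solve_linear_network(
    w_chem: np.ndarray, L_gap: np.ndarray, drive_input: np.ndarray
) -> np.ndarray:
    """Solve (I − W + L) V = drive_input for an arbitrary cell count."""
    n = drive_input.size
    A = np.eye(n) - np.asarray(w_chem, dtype=float) + np.asarray(L_gap, dtype=float)
    try:
        return np.linalg.solve(A, drive_input)
    except np.linalg.LinAlgError as e:
        raise NetworkSolveError(f"singular steady-state system: {e}") from e


def solve_network(
    config: NetworkConfig,
    drive_s: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Steady-state responses of the 8 cells to one input vector.

    Linear solve by default; with ``config.rectify`` a fixed-point
    iteration with half-wave rectification (responses clipped at zero) is
    run to ``tol``.
    """
    L = gap_laplacian(config.gap_edges, config.g)
    inp = config.drive @ np.asarray(drive_s, dtype=float)
    if not config.rectify:
        return solve_linear_network(config.w_chem, L, inp)
    V = np.zeros(8)
    for _ in range(max_iter):
        V_new = np.maximum(0.0, config.w_chem @ V - L @ V + inp)
        if np.max(np.abs(V_new - V)) < tol:
            return V_new
        V = V_new
    raise NetworkSolveError(f"rectified iteration did not converge in {max_iter} steps")


def condition_responses(config: NetworkConfig) -> pd.DataFrame:
    """Per-cell steady-state responses to the four optic-flow conditions."""
    out = {}
    for name, s in condition_drives().items():
        out[name] = solve_network(config, s)
    return pd.DataFrame(out, index=list(CELLS))


@dataclass
class DIResult:
    di: pd.Series  # per cell, in [−1, 1]
    of_rotation: pd.Series  # max−min over CW/CCW, ≥ 0
    of_translation: pd.Series  # max−min over fwd/bwd, ≥ 0
    degenerate: pd.Series  # True where both OF terms are 0 (DI set to 0)


def discrimination_index(responses: pd.DataFrame) -> DIResult:
    """Discrimination Index per cell from the four condition responses."""
    missing = set(CONDITIONS) - set(responses.columns)
    if missing:
        raise ValueError(f"missing condition responses: {sorted(missing)}")
    cw, ccw = responses["clockwise"], responses["counterclockwise"]
    fwd, bwd = responses["forward_translation"], responses["backward_translation"]
    of_rot = np.maximum(cw, ccw) - np.minimum(cw, ccw)
    of_tr = np.maximum(fwd, bwd) - np.minimum(fwd, bwd)
    denom = np.abs(of_tr) + np.abs(of_rot)
    degenerate = denom == 0
    di = (of_tr - of_rot) / denom.where(~degenerate, 1.0)
    di = di.where(~degenerate, 0.0)
    return DIResult(di=di, of_rotation=of_rot, of_translation=of_tr, degenerate=degenerate)


PERTURBATION_MODES = ("silence_HS_chem", "silence_H2_chem", "shakB", "kir_HS")


def perturb(config: NetworkConfig, mode: str) -> NetworkConfig:
    """Perturbed copy of the network; the original is untouched.

    * ``silence_HS_chem`` / ``silence_H2_chem`` — zero the chemical output
      weights of that cell class (columns of W), keeping gap junctions;
    * ``shakB`` — gap conductance to 0 (the mutant), chemistry intact;
    * ``kir_HS`` — HS outputs silenced chemically AND electrically.
    """
    if mode not in PERTURBATION_MODES:
        raise ValueError(f"unknown perturbation mode {mode!r}")
    W = config.w_chem.copy()
    edges = config.gap_edges
    g = config.g
    if mode in ("silence_HS_chem", "kir_HS"):
        for c in ("HS_L", "HS_R"):
            W[:, _idx(c)] = 0.0
    if mode == "silence_H2_chem":
        for c in ("H2_L", "H2_R"):
            W[:, _idx(c)] = 0.0
    if mode == "shakB":
        g = 0.0
    if mode == "kir_HS":
        edges = tuple(e for e in edges if "HS_L" not in e and "HS_R" not in e)
    return NetworkConfig(w_chem=W, drive=config.drive.copy(), gap_edges=edges,
                         g=g, rectify=config.rectify)


def di_vs_g_sweep(config: NetworkConfig, g_values: np.ndarray) -> pd.DataFrame:
    """DI of every cell across gap conductances (rows: g, columns: cells).

    Points where the steady state is unsolvable are returned as NaN rows
    (flagged in the ``solvable`` column).
    """
    rows = []
    for g in np.asarray(g_values, dtype=float):
        cfg = replace(config, w_chem=config.w_chem.copy(), drive=config.drive.copy(), g=float(g))
        try:
            di = discrimination_index(condition_responses(cfg)).di
            row = {"g": g, "solvable": True, **di.to_dict()}
        except NetworkSolveError:
            row = {"g": g, "solvable": False, **{c: np.nan for c in CELLS}}
        rows.append(row)
    return pd.DataFrame(rows)
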