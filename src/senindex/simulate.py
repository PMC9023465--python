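"""Synthetic tumor scRNA-seq generator with planted senescent cells.

Counts are negative binomial: gene-level baseline means are log-normal
around a global mean, with a shared dispersion. A configurable fraction of
cells is senescent; in those cells the NB means of senescence-marker and
SASP genes are multiplied by exp(lfc) and the means of cell-cycle genes by
exp(lfc_cellcycle) (negative for arrest). Mcl1 is elevated in all senescent
cells and Bcl2 in a configurable subset, giving the Bcl2+/Bcl2- structure
the stratification analyses expect. Effects act on NB means, so dispersion
semantics stay honest; an optional extra Bernoulli dropout layer can be
stacked on top.

Gene roles reuse the built-in signature symbols (Cdkn2a..., Cxcl1...,
Bcl2, Mcl1, compartment and gating markers), so downstream scoring
exercises the real symbol-intersection code paths. Cell-cycle genes are
synthetic symbols split into three overlapping stand-in collections (K, R,
WP) mimicking the partial overlap of the public cell-cycle gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, GeneSet, builtin_signatures

__all__ = ["SimConfig", "SimulationTruth", "simulate_tumor", "fixture_small",
           "standin_cellcycle_sets"]

_N_CELLCYCLE = 60
_MITO_GENES = ["mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp6", "mt-Cytb"]
_MARKER_GENES = ["Epcam", "Ptprc"]

# compartment mixture and marker elevation (4-fold)
_COMPARTMENT_PROBS = {"luminal": 0.7, "basal": 0.2, "seminal_vesicle": 0.1}
_COMPARTMENT_FOLD = 4.0


@dataclass
class SimConfig:
    """Study conditions for one simulated tumor."""

    n_cells: int = 2000
    n_genes: int = 1000
    frac_senescent: float = 0.20
    nb_mean: float = 0.5
    nb_dispersion: float = 2.0
    lfc_senescence_markers: float = 2.0
    lfc_cellcycle: float = -2.0
    lfc_sasp: float = 2.0
    lfc_mcl1: float = 1.0
    frac_bcl2_pos: float = 0.5
    dropout_extra: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        bad = []
        for name in ("frac_senescent", "frac_bcl2_pos"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad.append(name)
        if not 0.0 <= self.dropout_extra < 1.0:
            bad.append("dropout_extra")
        if self.nb_mean <= 0:
            bad.append("nb_mean")
        if self.nb_dispersion <= 0:
            bad.append("nb_dispersion")
        if self.n_cells < 8:
            bad.append("n_cells")
        if self.n_genes < 170:  # must hold every named role gene plus padding
            bad.append("n_genes")
        if bad:
            raise ValueError(f"invalid SimConfig fields: {bad}")


@dataclass
class SimulationTruth:
    """Planted ground truth aligned index-for-index with the count matrix."""

    is_senescent: np.ndarray          # bool per cell
    compartment: np.ndarray           # label per cell
    bcl2_pos: np.ndarray              # bool per cell (senescent subset)
    gene_role: pd.Series              # role per gene symbol
    realized_lfc: pd.Series           # log-fold-change applied in senescent cells
    config: SimConfig = field(repr=False, default=None)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "is_senescent": self.is_senescent,
            "compartment": self.compartment,
            "bcl2_pos": self.bcl2_pos,
        })


def standin_cellcycle_sets() -> dict[str, GeneSet]:
    """Three overlapping stand-in cell-cycle gene sets over the simulator's
    synthetic cell-cycle symbols (Ccg001..Ccg060)."""
    cc = [f"Ccg{i + 1:03d}" for i in range(_N_CELLCYCLE)]
    return {
        "K": GeneSet("K", cc[0:40], source="standin"),
        "R": GeneSet("R", cc[20:60], source="standin"),
        "WP": GeneSet("WP", cc[10:50], source="standin"),
    }


def _gene_table(cfg: SimConfig) -> tuple[pd.Index, pd.Series]:
    reg = builtin_signatures()
    roles: dict[str, str] = {}
    for g in reg["senescence_core"].genes:
        roles[g] = "senescence_marker"
    for g in reg["sasp"].genes:
        roles[g] = "sasp"
    for i in range(_N_CELLCYCLE):
        roles[f"Ccg{i + 1:03d}"] = "cellcycle"
    for name in ("anti_apoptosis", "pro_apoptosis", "necroptosis",
                 "ferroptosis", "parthanatos", "pyroptosis"):
        for g in reg[name].genes:
            roles.setdefault(g, "survival")
    for name in ("luminal", "basal", "seminal_vesicle"):
        for g in reg[name].genes:
            roles.setdefault(g, "compartment")
    for g in _MARKER_GENES:
        roles[g] = "marker"
    for g in _MITO_GENES:
        roles[g] = "mito"
    n_named = len(roles)
    if cfg.n_genes < n_named + 10:
        raise ValueError(
            f"n_genes={cfg.n_genes} too small for the {n_named} role genes"
        )
    for i in range(cfg.n_genes - n_named):
        roles[f"Gene{i + 1:04d}"] = "background"
    symbols = pd.Index(list(roles.keys()), name="symbol")
    return symbols, pd.Series(roles, name="role")


def simulate_tumor(cfg: SimConfig) -> tuple[CountMatrix, SimulationTruth]:
    """Draw one synthetic tumor. Fully reproducible under ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    symbols, role = _gene_table(cfg)
    n_genes = len(symbols)
    n_sen = int(round(cfg.n_cells * cfg.frac_senescent))
    is_sen = np.zeros(cfg.n_cells, dtype=bool)
    is_sen[:n_sen] = True
    rng.shuffle(is_sen)

    comps = list(_COMPARTMENT_PROBS)
    compartment = rng.choice(
        comps, size=cfg.n_cells, p=list(_COMPARTMENT_PROBS.values())
    ).astype(object)

    bcl2_pos = np.zeros(cfg.n_cells, dtype=bool)
    sen_idx = np.flatnonzero(is_sen)
    n_bpos = int(round(len(sen_idx) * cfg.frac_bcl2_pos))
    bcl2_pos[rng.choice(sen_idx, size=n_bpos, replace=False)] = True

    # gene-level baseline means: log-normal around nb_mean
    base = np.exp(rng.normal(np.log(cfg.nb_mean), 1.0, size=n_genes))
    # keep gating/compartment/mito machinery reliably detectable
    role_arr = role.to_numpy()
    base[role_arr == "marker"] = 2.0
    base[role_arr == "mito"] = np.maximum(base[role_arr == "mito"], 1.0)
    # canonical compartment markers share one baseline so the planted
    # 4-fold elevation, not baseline lottery, decides the compartment call
    base[role_arr == "compartment"] = 8.0
    # Mcl1 is broadly and highly expressed in tumor epithelium; Bcl2 is
    # detected in only a subset of cells
    base[symbols.get_loc("Mcl1")] = 3.0
    base[symbols.get_loc("Bcl2")] = 0.5

    lfc = pd.Series(0.0, index=symbols, name="realized_lfc")
    lfc[role_arr == "senescence_marker"] = cfg.lfc_senescence_markers
    lfc[role_arr == "sasp"] = cfg.lfc_sasp
    lfc[role_arr == "cellcycle"] = cfg.lfc_cellcycle
    if "Mcl1" in lfc.index:
        lfc["Mcl1"] = cfg.lfc_mcl1

    mu = np.tile(base, (cfg.n_cells, 1))
    mu[is_sen] *= np.exp(lfc.to_numpy())
    # Bcl2 follows the pro-survival effect size in its positive subset only
    j_bcl2 = symbols.get_loc("Bcl2")
    mu[:, j_bcl2] = base[j_bcl2]
    mu[bcl2_pos, j_bcl2] = base[j_bcl2] * np.exp(cfg.lfc_mcl1)
    # compartment markers 4-fold up in their own compartment
    reg = builtin_signatures()
    for comp in comps:
        cols = [symbols.get_loc(g) for g in reg[comp].genes]
        rows = compartment == comp
        mu[np.ix_(rows, cols)] *= _COMPARTMENT_FOLD
    # Ptprc marks immune cells only; epithelial simulation keeps it silent
    mu[:, symbols.get_loc("Ptprc")] = 0.0

    # NB(mean mu, dispersion theta) via gamma-Poisson mixture
    theta = cfg.nb_dispersion
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam)
    if cfg.dropout_extra > 0:
        keep = rng.random(counts.shape) >= cfg.dropout_extra
        counts = counts * keep

    genes = pd.DataFrame(
        {"biotype": "protein_coding", "is_mito": role_arr == "mito"}, index=symbols
    )
    genes["role"] = role_arr
    cells = pd.DataFrame(
        {"sample": "sim", "treatment": "none"},
        index=pd.Index([f"cell{i + 1:05d}" for i in range(cfg.n_cells)], name="barcode"),
    )
    cm = CountMatrix(sp.csr_matrix(counts), genes, cells)
    truth = SimulationTruth(
        is_senescent=is_sen,
        compartment=compartment,
        bcl2_pos=bcl2_pos,
        gene_role=role,
        realized_lfc=lfc,
        config=cfg,
    )
    return cm, truth


_FIXTURE_SEED = 20230


def fixture_small() -> tuple[CountMatrix, SimulationTruth]:
    """Pinned 200-cell x 300-gene dataset with strong effects, for docs and
    golden tests. Calling twice yields bit-identical matrices."""
    cfg = SimConfig(
        n_cells=200,
        n_genes=300,
        frac_senescent=0.20,
        nb_mean=0.5,
        nb_dispersion=2.0,
        lfc_senescence_markers=2.5,
        lfc_cellcycle=-2.5,
        lfc_sasp=2.5,
        lfc_mcl1=1.5,
        frac_bcl2_pos=0.5,
        dropout_extra=0.0,
        seed=_FIXTURE_SEED,
    )
    return simulate_tumor(cfg)
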