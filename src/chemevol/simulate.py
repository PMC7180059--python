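"""Synthetic-data generators for the full pipeline.

Everything the downstream stages consume can be generated here with the
statistical structure those stages assume: an ultrametric pure-birth species
tree, tip traits evolved under Brownian motion (or without signal), multi-
experiment species-by-compound intensity matrices following the combining
mixed model, LC-MS feature tables with parental adduct pairs, genin and
sugar-loss fragments, isomers, and noise peaks, and 4PL microplate absorbance
series with an ouabain calibration. A :class:`GroundTruth` records every
latent quantity so recovery can be asserted exactly.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .library import CompoundLibrary, default_library
from .masses import PROTON_MASS, WATER_MASS, mz_mh_neg, mz_mh_pos, mz_mna_pos


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Controls for the profile/trait simulators.

    Defaults emulate the study design this package targets: 48 species, three
    independent experiments with modest fixed offsets, ~30 compounds with
    phylogenetically structured species-by-compound means, and log-scale
    noise at the cell (species x compound x experiment) and replicate levels.
    """

    n_tips: int = 48
    birth_rate: float = 1.0
    sigma2: float = 1.0  # Brownian rate, trait units^2 per unit depth
    n_compounds: int = 30
    n_experiments: int = 3
    #: None derives the default pattern (0, +0.5, -0.5, +0.5, ...), which for
    #: the default three experiments is (0, 0.5, -0.5)
    experiment_effects: Optional[Sequence[float]] = None
    noise_sd_cell: float = 0.3  # SD of the cell random effect w_sce
    noise_sd_rep: float = 0.2  # SD of the replicate residual
    n_replicates: int = 2
    mu_mean: float = 4.0  # grand mean of per-compound log intensities
    mu_sd: float = 1.0  # spread of per-compound means
    phylo_profiles: bool = True  # BM-structured u_sc (per compound)
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be at least 2")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.n_compounds < 1 or self.n_experiments < 1 or self.n_replicates < 1:
            raise ValueError("n_compounds, n_experiments, n_replicates must be >= 1")
        for name in ("noise_sd_cell", "noise_sd_rep", "mu_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.experiment_effects is None:
            self.experiment_effects = tuple(
                0.0 if e == 0 else (0.5 if e % 2 else -0.5)
                for e in range(self.n_experiments)
            )
        self.experiment_effects = tuple(float(b) for b in self.experiment_effects)
        if len(self.experiment_effects) != self.n_experiments:
            raise ValueError("experiment_effects length must equal n_experiments")


@dataclass
class TrueCompound:
    """A concrete synthetic molecule backing one profile column."""

    compound_id: str
    compound_class: str  # "cardenolide" | "glucosinolate"
    genin: Optional[str]
    sugars: tuple  # ordered inner -> outer
    acetyl: bool
    neutral_mass: float
    rt: float
    isomer_index: int
    name: Optional[str] = None  # library name for glucosinolates
    na_to_h_ratio: float = 0.6


@dataclass
class GroundTruth:
    """Latent state behind one synthetic dataset."""

    tree: Optional[dendropy.Tree] = None
    traits: Optional[pd.DataFrame] = None
    mu: Optional[pd.Series] = None  # per-compound grand mean (log scale)
    beta: Optional[pd.Series] = None  # per-experiment fixed offsets
    u: Optional[pd.DataFrame] = None  # species x compound main random effects
    cell_means: Optional[pd.DataFrame] = None  # mu + u
    long: Optional[pd.DataFrame] = None  # replicate-level log intensities
    compounds: list = field(default_factory=list)  # TrueCompound panel
    feature_map: dict = field(default_factory=dict)  # feature_id -> compound_id|None
    ic50s: Optional[pd.Series] = None  # molar equivalents of the x=0 well
    x_mid: Optional[pd.Series] = None  # dilution-scale midpoints per extract

    def to_json(self, path) -> None:
        def df(x):
            return None if x is None else json.loads(x.to_json())

        payload = {
            "tree": self.tree.as_string(schema="newick") if self.tree else None,
            "traits": df(self.traits),
            "mu": df(self.mu),
            "beta": df(self.beta),
            "u": df(self.u),
            "cell_means": df(self.cell_means),
            "compounds": [
                {
                    "compound_id": c.compound_id,
                    "compound_class": c.compound_class,
                    "genin": c.genin,
                    "sugars": list(c.sugars),
                    "acetyl": c.acetyl,
                    "neutral_mass": c.neutral_mass,
                    "rt": c.rt,
                    "isomer_index": c.isomer_index,
                    "name": c.name,
                }
                for c in self.compounds
            ],
            "feature_map": self.feature_map,
            "ic50s": df(self.ic50s),
            "x_mid": df(self.x_mid),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# --------------------------------------------------------------------------
# tree and traits
# --------------------------------------------------------------------------


def simulate_tree(
    n_tips: int, birth_rate: float = 1.0, seed: Optional[int] = None
) -> dendropy.Tree:
    """Simulate a rooted, binary, ultrametric pure-birth (Yule) tree.

    The tree is rescaled to unit root depth: only relative branch lengths
    matter for the downstream statistics (K, PGLS, ND, ES).
    """
    if n_tips < 2:
        raise ValueError("n_tips must be at least 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    # deterministic tip labels sp01..spNN in leaf order
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:02d}"
    # drop any root edge, enforce exact ultrametricity (floating-point drift
    # from the simulator), then rescale to unit depth
    tree.seed_node.edge.length = None
    depths = {leaf: leaf.distance_from_root() for leaf in tree.leaf_node_iter()}
    max_depth = max(depths.values())
    for leaf, d in depths.items():
        leaf.edge.length += max_depth - d
    # the simulator cuts at the n-th birth, leaving a zero pendant cherry;
    # extend to the present by the memoryless wait for the (uncut) next event
    t_extra = rng.expovariate(n_tips * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += t_extra
    max_depth += t_extra
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= max_depth
    tree.is_rooted = True
    return tree


def simulate_traits(
    tree: dendropy.Tree,
    model: str = "bm",
    sigma2: float = 1.0,
    n_traits: int = 1,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate tip traits under Brownian motion or without signal.

    ``model="bm"`` draws multivariate normal tips with covariance
    ``sigma2 * V(tree)``; ``model="white"`` draws iid normal tips with
    variance ``sigma2`` (no phylogenetic structure). Returns a tips x traits
    DataFrame.
    """
    from .phylo import brownian_cov

    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if model not in ("bm", "white"):
        raise ValueError(f"unknown trait model {model!r}; use 'bm' or 'white'")
    rng = np.random.default_rng(seed)
    V = brownian_cov(tree)
    labels = list(V.index)
    z = rng.standard_normal((len(labels), n_traits))
    if model == "bm":
        L = np.linalg.cholesky(V.to_numpy())
        x = np.sqrt(sigma2) * (L @ z)
    else:
        x = np.sqrt(sigma2) * z
    return pd.DataFrame(
        x, index=labels, columns=[f"trait_{i + 1}" for i in range(n_traits)]
    )


# --------------------------------------------------------------------------
# species-by-compound profiles
# --------------------------------------------------------------------------


def simulate_profiles(
    tree: dendropy.Tree,
    config: SimConfig,
    seed: Optional[int] = None,
):
    """Simulate per-experiment species-by-compound log-intensity matrices.

    Observed log intensities follow the combining model
    ``y = mu_c + beta_e + u_sc + w_sce + eps`` with the configured SDs; the
    main random effect ``u_sc`` is Brownian-structured per compound when
    ``config.phylo_profiles`` (rate ``config.sigma2``), otherwise iid normal
    with the same marginal variance. Returns ``(matrices, ground_truth)``
    where ``matrices`` holds one species x compound DataFrame per experiment
    (replicate means) and the ground truth carries the replicate-level long
    table plus all latent components.
    """
    from .phylo import brownian_cov

    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    species = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    n_s, n_c = len(species), config.n_compounds
    compounds = [f"compound_{j + 1:02d}" for j in range(n_c)]

    mu = pd.Series(
        config.mu_mean + config.mu_sd * rng.standard_normal(n_c),
        index=compounds,
        name="mu",
    )
    beta = pd.Series(
        config.experiment_effects,
        index=[f"exp{e + 1}" for e in range(config.n_experiments)],
        name="beta",
    )
    if config.phylo_profiles:
        V = brownian_cov(tree).loc[species, species].to_numpy()
        L = np.linalg.cholesky(V)
        u_mat = np.sqrt(config.sigma2) * (L @ rng.standard_normal((n_s, n_c)))
    else:
        u_mat = np.sqrt(config.sigma2) * rng.standard_normal((n_s, n_c))
    u = pd.DataFrame(u_mat, index=species, columns=compounds)
    cell_means = u.add(mu, axis=1)

    rows = []
    matrices = []
    for e, exp in enumerate(beta.index):
        w = config.noise_sd_cell * rng.standard_normal((n_s, n_c))
        y_reps = np.zeros((n_s, n_c))
        for r in range(config.n_replicates):
            eps = config.noise_sd_rep * rng.standard_normal((n_s, n_c))
            y = cell_means.to_numpy() + beta.iloc[e] + w + eps
            y_reps += y
            for i, sp in enumerate(species):
                for j, cmp_ in enumerate(compounds):
                    rows.append(
                        (f"{sp}:{exp}:rep{r + 1}", sp, exp, cmp_, float(y[i, j]))
                    )
        matrices.append(
            pd.DataFrame(
                y_reps / config.n_replicates, index=species, columns=compounds
            )
        )

    long = pd.DataFrame(
        rows, columns=["sample_id", "species", "experiment", "compound", "y"]
    )
    # raw-scale ion counts consistent with the log(+0.1) transform
    long["intensity"] = np.maximum(np.exp(long["y"]) - 0.1, 0.0)
    gt = GroundTruth(
        tree=tree, mu=mu, beta=beta, u=u, cell_means=cell_means, long=long
    )
    return matrices, gt


# --------------------------------------------------------------------------
# LC-MS feature tables
# --------------------------------------------------------------------------


@dataclass
class MSParams:
    """Controls for the synthetic LC-MS feature generator.

    RT domain 0-15 min and m/z domain 50-1200 match the chromatographic
    gradient and scan range the analyses assume. Fragment yields are fixed
    fractions of the parent [M+H]+ intensity. ``noise_peaks`` uniform-random
    peaks are added per sample; jitter SDs perturb measured m/z and RT.
    """

    rt_min: float = 0.5
    rt_max: float = 14.5
    mz_min: float = 50.0
    mz_max: float = 1200.0
    genin_fragment_yield: float = 0.30
    water_loss_yield: float = 0.15
    sugar_loss_yield: float = 0.20
    diag_fragment_yield: float = 0.25
    noise_peaks: int = 50
    mz_jitter_sd: float = 0.0
    rt_jitter_sd: float = 0.0
    n_isomer_pairs: int = 2
    n_cardenolides: int = 20
    n_glucosinolates: int = 8


def make_compound_panel(
    library: CompoundLibrary,
    ms_params: MSParams,
    seed: Optional[int] = None,
) -> list:
    """Draw a panel of concrete molecules to back profile columns.

    Cardenolides combine a random genin with 0-2 sugar residues and an
    optional acetyl on the first sugar; glucosinolates are drawn from the
    library targets. ``n_isomer_pairs`` cardenolides are duplicated at a
    distinct retention time to emulate isomeric sugars of equal mass. RT
    slots are spaced widely enough that co-elution groups never overlap.
    """
    rng = np.random.default_rng(seed)
    n_card = ms_params.n_cardenolides
    n_gls = min(ms_params.n_glucosinolates, len(library.glucosinolates))
    n_total = n_card + ms_params.n_isomer_pairs + n_gls
    slots = np.linspace(ms_params.rt_min, ms_params.rt_max, n_total)
    rng.shuffle(slots)
    slot_iter = iter(slots)

    panel = []
    for k in range(n_card):
        genin = library.genins[int(rng.integers(len(library.genins)))]
        n_sugars = int(rng.integers(0, 3))
        sugars = tuple(
            library.sugars[int(rng.integers(len(library.sugars)))].name
            for _ in range(n_sugars)
        )
        acetyl = bool(n_sugars and rng.random() < 0.25)
        mass = (
            genin.mass
            + sum(library.sugar_by_name(s).loss_mass for s in sugars)
            + (library.acetyl_mass if acetyl else 0.0)
        )
        panel.append(
            TrueCompound(
                compound_id=f"compound_{k + 1:02d}",
                compound_class="cardenolide",
                genin=genin.name,
                sugars=sugars,
                acetyl=acetyl,
                neutral_mass=mass,
                rt=float(next(slot_iter)),
                isomer_index=1,
                na_to_h_ratio=float(rng.uniform(0.3, 2.0)),
            )
        )
    for j in range(ms_params.n_isomer_pairs):
        src = panel[int(rng.integers(len(panel)))]
        panel.append(
            TrueCompound(
                compound_id=f"compound_{n_card + j + 1:02d}",
                compound_class="cardenolide",
                genin=src.genin,
                sugars=src.sugars,
                acetyl=src.acetyl,
                neutral_mass=src.neutral_mass,
                rt=float(next(slot_iter)),
                isomer_index=2,  # provisional; ordered below
                na_to_h_ratio=float(rng.uniform(0.3, 2.0)),
            )
        )
    gls_choice = rng.choice(len(library.glucosinolates), size=n_gls, replace=False)
    for j, gi in enumerate(gls_choice):
        target = library.glucosinolates[int(gi)]
        panel.append(
            TrueCompound(
                compound_id=f"compound_{n_card + ms_params.n_isomer_pairs + j + 1:02d}",
                compound_class="glucosinolate",
                genin=None,
                sugars=(),
                acetyl=False,
                neutral_mass=target.mass,
                rt=float(next(slot_iter)),
                isomer_index=1,
                name=target.name,
            )
        )
    # isomer indices ascend with RT within each shared (genin, mass) group
    groups = {}
    for c in panel:
        if c.compound_class == "cardenolide":
            groups.setdefault((c.genin, round(c.neutral_mass, 3)), []).append(c)
    for members in groups.values():
        members.sort(key=lambda c: c.rt)
        for idx, c in enumerate(members, start=1):
            c.isomer_index = idx
    return panel


def simulate_feature_table(
    library: CompoundLibrary,
    species_profiles: pd.DataFrame,
    panel: Sequence[TrueCompound],
    ms_params: Optional[MSParams] = None,
    seed: Optional[int] = None,
):
    """Emit an LC-MS feature table realizing species-by-compound abundances.

    ``species_profiles`` is a species x compound matrix of raw-scale
    abundances whose columns name members of ``panel``. For every nonzero
    species-compound: cardenolides produce the [M+H]+/[M+Na]+ parental pair,
    genin and water-loss fragments, and (for di-glycosides) the outer-sugar
    loss, all at the compound's RT; glucosinolates produce [M-H]- plus
    diagnostic core fragments. Noise peaks are uniform over the m/z x RT
    domain. Returns ``(features, ground_truth)`` with
    ``ground_truth.feature_map`` sending every feature id to its compound id
    (None for noise).
    """
    ms_params = ms_params or MSParams()
    rng = np.random.default_rng(seed)
    by_id = {c.compound_id: c for c in panel}
    missing = [c for c in species_profiles.columns if c not in by_id]
    if missing:
        raise KeyError(f"profiled compounds absent from panel/library: {missing}")

    feature_registry = {}  # (mode, round mz, round rt, kind) -> feature_id
    feature_map = {}
    rows = []
    counter = [0]

    def feature_id_for(mode, mz, rt, kind, compound_id):
        key = (mode, round(mz, 4), round(rt, 3), kind)
        if key not in feature_registry:
            counter[0] += 1
            fid = f"F{counter[0]:05d}"
            feature_registry[key] = fid
            feature_map[fid] = compound_id if kind in ("MH", "MNa", "M-H") else None
            # fragments trace to their parent compound too
            if kind not in ("MH", "MNa", "M-H", "noise"):
                feature_map[fid] = compound_id
        return feature_registry[key]

    def emit(sample, mode, mz, rt, intensity, kind, compound_id):
        if intensity <= 0:
            return
        mzj = mz + (rng.normal(0, ms_params.mz_jitter_sd) if ms_params.mz_jitter_sd else 0.0)
        rtj = rt + (rng.normal(0, ms_params.rt_jitter_sd) if ms_params.rt_jitter_sd else 0.0)
        fid = feature_id_for(mode, mz, rt, kind, compound_id)
        rows.append((fid, mzj, max(rtj, 0.0), float(intensity), sample, mode))

    for sample in species_profiles.index:
        for cid in species_profiles.columns:
            abundance = float(species_profiles.loc[sample, cid])
            if abundance <= 0:
                continue
            c = by_id[cid]
            if c.compound_class == "cardenolide":
                h_int = abundance
                na_int = abundance * c.na_to_h_ratio
                emit(sample, "positive", mz_mh_pos(c.neutral_mass), c.rt, h_int, "MH", cid)
                emit(sample, "positive", mz_mna_pos(c.neutral_mass), c.rt, na_int, "MNa", cid)
                genin = library.genin_by_name(c.genin)
                emit(
                    sample, "positive", mz_mh_pos(genin.mass), c.rt,
                    abundance * ms_params.genin_fragment_yield, "genin", cid,
                )
                emit(
                    sample, "positive", mz_mh_pos(genin.mass) - WATER_MASS, c.rt,
                    abundance * ms_params.water_loss_yield, "genin-H2O", cid,
                )
                if len(c.sugars) == 2:
                    outer = library.sugar_by_name(c.sugars[-1])
                    emit(
                        sample, "positive",
                        mz_mh_pos(c.neutral_mass - outer.loss_mass), c.rt,
                        abundance * ms_params.sugar_loss_yield, "sugar-loss", cid,
                    )
            else:
                emit(sample, "negative", mz_mh_neg(c.neutral_mass), c.rt, abundance, "M-H", cid)
                for k, frag in enumerate(library.diagnostic_fragments_neg[:3]):
                    emit(
                        sample, "negative", frag, c.rt,
                        abundance * ms_params.diag_fragment_yield, f"diag{k}", cid,
                    )
        for _ in range(ms_params.noise_peaks):
            counter[0] += 1
            fid = f"F{counter[0]:05d}"
            feature_map[fid] = None
            mode = "positive" if rng.random() < 0.5 else "negative"
            rows.append(
                (
                    fid,
                    float(rng.uniform(ms_params.mz_min, ms_params.mz_max)),
                    float(rng.uniform(ms_params.rt_min, ms_params.rt_max)),
                    float(rng.uniform(10, 1000)),
                    sample,
                    mode,
                )
            )

    features = pd.DataFrame(
        rows, columns=["feature_id", "mz", "rt", "intensity", "sample_id", "mode"]
    )
    gt = GroundTruth(compounds=list(panel), feature_map=feature_map)
    return features, gt


# --------------------------------------------------------------------------
# microplate dose-response data
# --------------------------------------------------------------------------


@dataclass
class PlateParams:
    """4PL plate generator controls.

    ``A``/``B`` are the active and fully inhibited absorbance asymptotes,
    ``scal`` the shared shape on the log10-concentration scale,
    ``ouabain_ic50`` the molar midpoint of the calibration curve,
    ``dilutions`` the sample dilution factors (1:1, 1:5, 1:50, 1:500), and
    ``calib_concs`` the ouabain calibration series (10^-3..10^-8 M).
    """

    A: float = 1.0
    B: float = 0.05
    scal: float = 0.5
    noise_sd: float = 0.0
    background: float = 0.08
    ouabain_ic50: float = 1e-7
    dilutions: tuple = (1.0, 5.0, 50.0, 500.0)
    calib_concs: tuple = (1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8)


def four_pl(x, A, B, x_mid, scal):
    """4-parameter logistic: A + (B - A) / (1 + exp((x_mid - x) / scal))."""
    from scipy.special import expit

    x = np.asarray(x, dtype=float)
    return A + (B - A) * expit((x - x_mid) / scal)


def simulate_plate(
    true_ic50s,
    plate_params: Optional[PlateParams] = None,
    seed: Optional[int] = None,
):
    """Simulate a 96-well inhibition plate.

    ``true_ic50s`` maps extract ids to the molar ouabain-equivalent
    concentration of the undiluted (1:1) well. Sample wells at the
    configured dilution factors and a full ouabain calibration series follow
    the 4PL on the log10-concentration scale plus the additive background
    and Gaussian noise. Returns ``(plate, ground_truth)``; ``plate`` has
    columns ``extract_id, role, x, absorbance, background`` where ``x`` is
    log10 dilution factor for samples and log10 molarity for calibration.
    """
    p = plate_params or PlateParams()
    rng = np.random.default_rng(seed)
    ic50s = pd.Series(dict(true_ic50s), dtype=float)
    if (ic50s <= 0).any():
        raise ValueError("true IC50 equivalents must be positive")
    log_ic50_ou = np.log10(p.ouabain_ic50)

    rows = []
    x_mid = {}
    for extract, c0 in ic50s.items():
        x_mid[extract] = float(np.log10(c0) - log_ic50_ou)  # dilution-scale midpoint
        for d in p.dilutions:
            conc = np.log10(c0 / d)
            signal = four_pl(conc, p.A, p.B, log_ic50_ou, p.scal)
            noise = rng.normal(0, p.noise_sd) if p.noise_sd else 0.0
            rows.append(
                (
                    extract,
                    "sample",
                    float(np.log10(d)),
                    float(signal + p.background + noise),
                    float(p.background),
                )
            )
    for conc in p.calib_concs:
        x = float(np.log10(conc))
        signal = four_pl(x, p.A, p.B, log_ic50_ou, p.scal)
        noise = rng.normal(0, p.noise_sd) if p.noise_sd else 0.0
        rows.append(
            ("ouabain", "calibration", x, float(signal + p.background + noise),
             float(p.background))
        )
    plate = pd.DataFrame(
        rows, columns=["extract_id", "role", "x", "absorbance", "background"]
    )
    gt = GroundTruth(ic50s=ic50s, x_mid=pd.Series(x_mid, name="x_mid"))
    return plate, gt
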