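"""Rule-based annotation of cardenolides and glucosinolates from LC-MS
feature tables.

A feature table is a long-format :class:`pandas.DataFrame` with columns
``feature_id, mz, rt, intensity, sample_id, mode`` where one ``feature_id``
identifies one (m/z, RT, mode) peak observed across samples.

Cardenolides (positive mode) are found genin-first: a chromatographic peak
group is a candidate when it contains characteristic genin fragments
([genin+H]+ and water-loss ions); the parental mass then comes from the
[M+H]+/[M+Na]+ adduct pair separated by mass(Na)-mass(H) = 21.9819 m/z, and
the glycoside chain (0-2 residues, optional acetylation of the inner sugar)
is solved from the neutral-mass difference to the genin plus observed
outer-sugar-loss fragments. Glucosinolates (negative mode) are matched by
exact [M-H]- mass against the library; unmatched parents co-eluting with
enough diagnostic core fragments are flagged as unknown candidates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import CompoundLibrary
from .masses import (
    NA_H_SPACING,
    PROTON_MASS,
    WATER_MASS,
    mz_mh_neg,
    mz_mh_pos,
    neutral_from_mh_neg,
    neutral_from_mh_pos,
)

logger = logging.getLogger(__name__)

#: QTOF-appropriate defaults; both configurable in every operation.
DEFAULT_MZ_TOL = 0.005
DEFAULT_RT_TOL = 0.05

FEATURE_COLUMNS = ["feature_id", "mz", "rt", "intensity", "sample_id", "mode"]


class AnnotationError(ValueError):
    """No residue combination explains a parental mass."""


class ConsistencyError(RuntimeError):
    """Annotations reference features absent from the feature table."""


@dataclass
class AnnotatedCompound:
    """One annotated defense compound (possibly one of several isomers)."""

    compound_id: str
    compound_class: str  # "cardenolide" | "glucosinolate"
    genin: str | None
    sugars: tuple  # ordered inner -> outer, 0-2 entries
    acetyl: bool
    neutral_mass: float
    rt: float
    isomer_index: int = 1
    adducts: dict = field(default_factory=dict)  # adduct label -> feature_id
    name: str | None = None
    order_resolved: bool = True

    @property
    def chain_length(self) -> int:
        return len(self.sugars)


def validate_features(features: pd.DataFrame, mode: str | None = None) -> pd.DataFrame:
    """Check feature-table schema and invariants; optionally require one mode."""
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    if len(features) and (features["intensity"] < 0).any():
        raise ValueError("intensities must be non-negative")
    if len(features) and (features["rt"] < 0).any():
        raise ValueError("retention times must be non-negative")
    if mode is not None and len(features) and (features["mode"] != mode).any():
        raise ValueError(f"expected {mode}-mode features only")
    return features


def unique_features(features: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-sample rows to one row per feature with total intensity."""
    if not len(features):
        return pd.DataFrame(columns=["feature_id", "mz", "rt", "mode", "intensity"])
    grouped = features.groupby("feature_id", sort=True).agg(
        mz=("mz", "first"),
        rt=("rt", "first"),
        mode=("mode", "first"),
        intensity=("intensity", "sum"),
    )
    return grouped.reset_index()


def find_adduct_pairs(
    features: pd.DataFrame,
    mz_tol: float = DEFAULT_MZ_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
) -> list:
    """Pair [M+H]+ and [M+Na]+ adducts of intact molecules.

    Returns a list of ``(h_feature_id, na_feature_id, neutral_mass)`` where the
    m/z spacing matches mass(Na)-mass(H) within ``mz_tol`` and the features
    co-elute within ``rt_tol``. Each feature joins at most one pair; conflicts
    are resolved greedily by summed pair intensity, ties by lexically smaller
    feature-id pair.
    """
    validate_features(features, mode="positive")
    uf = unique_features(features)
    mz = uf["mz"].to_numpy()
    rt = uf["rt"].to_numpy()
    inten = uf["intensity"].to_numpy()
    fid = uf["feature_id"].to_numpy()

    candidates = []
    for i in range(len(uf)):
        dmz = mz - mz[i] - NA_H_SPACING
        drt = np.abs(rt - rt[i])
        for j in np.nonzero((np.abs(dmz) <= mz_tol) & (drt <= rt_tol))[0]:
            if j == i:
                continue
            candidates.append(
                (inten[i] + inten[j], (str(fid[i]), str(fid[j])), i, int(j))
            )
    # greedy by intensity (desc), deterministic tie-break by feature-id pair
    candidates.sort(key=lambda c: (-c[0], c[1]))
    used = set()
    pairs = []
    for _, _, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        pairs.append((fid[i], fid[j], float(neutral_from_mh_pos(mz[i]))))
    return pairs


def detect_genin_fragments(
    feature_group: pd.DataFrame,
    library: CompoundLibrary,
    mz_tol: float = DEFAULT_MZ_TOL,
    max_water_losses: int = 2,
) -> list:
    """Genin candidates supported by co-eluting fragment ions.

    A genin is a candidate when the group contains [genin+H]+ or
    [genin+H-k*H2O]+ for k up to ``max_water_losses``. Returns
    ``(genin_name, n_matched_fragments)`` sorted by descending evidence, then
    by name.
    """
    if not len(feature_group):
        return []
    mz = feature_group["mz"].to_numpy()
    out = []
    for genin in library.genins:
        n = 0
        for k in range(max_water_losses + 1):
            target = mz_mh_pos(genin.mass) - k * WATER_MASS
            if np.any(np.abs(mz - target) <= mz_tol):
                n += 1
        if n:
            out.append((genin.name, n))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def _chain_combinations(library: CompoundLibrary, max_sugars: int = 2):
    """All sugar multisets of size 0..max_sugars crossed with the acetyl flag."""
    for k in range(max_sugars + 1):
        for combo in itertools.combinations_with_replacement(library.sugars, k):
            for acetyl in (False, True):
                if acetyl and k == 0:
                    continue  # acetylation sits on the first sugar moiety
                yield combo, acetyl


def infer_glycoside_chain(
    neutral_mass: float,
    genin,
    feature_group: pd.DataFrame,
    library: CompoundLibrary,
    mz_tol: float = DEFAULT_MZ_TOL,
):
    """Solve the glycoside chain linking a genin to a parental mass.

    Finds the sugar multiset (at most two residues) and acetyl flag whose
    anhydro masses close the genin-to-parent mass balance within ``mz_tol``.
    The residue order of a di-glycoside is fixed by an observed
    [parent - outer sugar + H]+ fragment; without such a fragment the order
    falls back to a deterministic convention and ``order_resolved`` is False.

    Returns ``(ordered_sugars, acetyl_flag, order_resolved)``.

    Raises
    ------
    AnnotationError
        If no residue combination matches.
    """
    if isinstance(genin, str):
        genin = library.genin_by_name(genin)
    delta = neutral_mass - genin.mass
    if delta < -mz_tol:
        raise AnnotationError(
            f"parental mass {neutral_mass:.4f} below genin {genin.name} mass"
        )
    mz = feature_group["mz"].to_numpy() if len(feature_group) else np.array([])

    def outer_loss_order(combo):
        """Residue order implied by an observed [parent - outer sugar]+ ion."""
        for outer, inner in itertools.permutations(combo, 2):
            frag = mz_mh_pos(neutral_mass - outer.loss_mass)
            if len(mz) and np.any(np.abs(mz - frag) <= mz_tol):
                return (inner.name, outer.name)
        return None

    matches = []
    for combo, acetyl in _chain_combinations(library):
        expected = sum(s.loss_mass for s in combo) + (
            library.acetyl_mass if acetyl else 0.0
        )
        err = abs(delta - expected)
        if err <= mz_tol:
            order = outer_loss_order(combo) if len(combo) == 2 else None
            matches.append((err, order, len(combo), acetyl, combo))
    if not matches:
        raise AnnotationError(
            f"no sugar/acetyl combination explains Δm = {delta:.4f} "
            f"for genin {genin.name}"
        )
    # mass-degenerate residue combinations (e.g. hexose + dideoxyhexose vs
    # two deoxyhexoses) are told apart by the observed outer-sugar loss;
    # remaining ties break deterministically: fewest residues, no acetyl,
    # sugar names
    matches.sort(
        key=lambda m: (
            round(m[0], 9),
            m[1] is None,
            m[2],
            m[3],
            tuple(s.name for s in m[4]),
        )
    )
    _, order, _, acetyl, combo = matches[0]
    if len(combo) < 2:
        return tuple(s.name for s in combo), acetyl, True
    if order is not None:
        return order, acetyl, True
    return tuple(sorted(s.name for s in combo)), acetyl, False


def _rt_group(uf: pd.DataFrame, rt_center: float, rt_tol: float) -> pd.DataFrame:
    return uf[np.abs(uf["rt"] - rt_center) <= rt_tol]


def _library_parent_masses(library: CompoundLibrary, max_sugars: int = 2):
    """Enumerated neutral masses of all library genin + chain combinations."""
    out = []
    for genin in library.genins:
        for combo, acetyl in _chain_combinations(library, max_sugars):
            mass = (
                genin.mass
                + sum(s.loss_mass for s in combo)
                + (library.acetyl_mass if acetyl else 0.0)
            )
            out.append((mass, genin.name))
    return out


def annotate_cardenolides(
    features: pd.DataFrame,
    library: CompoundLibrary,
    mz_tol: float = DEFAULT_MZ_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
    require_pair: bool = True,
) -> list:
    """Annotate cardenolides from a positive-mode feature table.

    Adduct pairing, genin-fragment detection, and chain inference are run per
    chromatographic peak group; compounds sharing a neutral mass (within
    ``2 * mz_tol``) and genin but separated in retention time are indexed as
    isomers in ascending RT. With ``require_pair=False``, single [M+H]+
    features whose implied neutral mass matches an enumerated library
    glycoside are accepted without a sodium partner (genin fragments are
    still required). Unannotatable groups are logged and skipped.
    """
    validate_features(features, mode="positive")
    uf = unique_features(features)
    pairs = find_adduct_pairs(features, mz_tol=mz_tol, rt_tol=rt_tol)
    by_id = uf.set_index("feature_id")

    parents = []  # (neutral_mass, rt, adducts dict)
    claimed = set()
    for h_id, na_id, neutral in pairs:
        rt = float(by_id.loc[h_id, "rt"])
        parents.append((neutral, rt, {"[M+H]+": h_id, "[M+Na]+": na_id}))
        claimed.update((h_id, na_id))

    if not require_pair:
        lib_masses = _library_parent_masses(library)
        for _, row in uf.iterrows():
            if row["feature_id"] in claimed:
                continue
            neutral = neutral_from_mh_pos(row["mz"])
            if any(abs(neutral - m) <= mz_tol for m, _ in lib_masses):
                parents.append(
                    (float(neutral), float(row["rt"]), {"[M+H]+": row["feature_id"]})
                )

    annotations = []
    for neutral, rt, adducts in parents:
        group = _rt_group(uf, rt, rt_tol)
        genin_candidates = detect_genin_fragments(group, library, mz_tol=mz_tol)
        if not genin_candidates:
            logger.info(
                "no genin fragments for parent m=%.4f at rt=%.2f; skipped",
                neutral,
                rt,
            )
            continue
        annotated = None
        for genin_name, _ in genin_candidates:
            try:
                sugars, acetyl, resolved = infer_glycoside_chain(
                    neutral, genin_name, group, library, mz_tol=mz_tol
                )
            except AnnotationError:
                continue
            annotated = AnnotatedCompound(
                compound_id="",
                compound_class="cardenolide",
                genin=genin_name,
                sugars=sugars,
                acetyl=acetyl,
                neutral_mass=neutral,
                rt=rt,
                adducts=adducts,
                order_resolved=resolved,
            )
            break
        if annotated is None:
            logger.info(
                "no chain solution for parent m=%.4f at rt=%.2f; skipped", neutral, rt
            )
            continue
        annotations.append(annotated)

    _assign_isomer_indices(annotations, mass_tol=2 * mz_tol, rt_tol=rt_tol)
    annotations.sort(key=lambda a: (a.genin or "", a.neutral_mass, a.rt))
    for a in annotations:
        suffix = f"-iso{a.isomer_index}" if a.isomer_index > 1 else ""
        chain = "+".join(a.sugars) if a.sugars else "free"
        ac = "+Ac" if a.acetyl else ""
        a.compound_id = f"card:{a.genin}:{chain}{ac}:m{a.neutral_mass:.4f}{suffix}"
        a.name = a.compound_id
    return annotations


def _assign_isomer_indices(annotations, mass_tol, rt_tol):
    """Number compounds sharing (class, genin, neutral mass) by ascending RT."""
    keyed = {}
    for a in annotations:
        placed = False
        for key, members in keyed.items():
            cls, genin, mass = key
            if (
                cls == a.compound_class
                and genin == (a.genin or "")
                and abs(mass - a.neutral_mass) <= mass_tol
            ):
                members.append(a)
                placed = True
                break
        if not placed:
            keyed[(a.compound_class, a.genin or "", a.neutral_mass)] = [a]
    for members in keyed.values():
        members.sort(key=lambda a: a.rt)
        for idx, a in enumerate(members, start=1):
            a.isomer_index = idx


def screen_glucosinolates(
    features: pd.DataFrame,
    library: CompoundLibrary,
    mz_tol: float = DEFAULT_MZ_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
    min_diag: int = 2,
) -> list:
    """Screen a negative-mode feature table for glucosinolates.

    Features matching a library [M-H]- mass within ``mz_tol`` are annotated
    by name; remaining parents co-eluting with at least ``min_diag``
    diagnostic core fragments become unknown glucosinolate candidates.
    Features at a shared neutral mass but distinct RT get isomer indices.
    """
    validate_features(features, mode="negative")
    uf = unique_features(features)
    mz = uf["mz"].to_numpy()
    diag = np.asarray(library.diagnostic_fragments_neg)
    is_diag = np.zeros(len(uf), dtype=bool)
    for d in diag:
        is_diag |= np.abs(mz - d) <= mz_tol

    annotations = []
    matched = np.zeros(len(uf), dtype=bool)
    for target in library.glucosinolates:
        target_mz = mz_mh_neg(target.mass)
        hits = np.nonzero(np.abs(mz - target_mz) <= mz_tol)[0]
        for i in hits:
            matched[i] = True
            row = uf.iloc[i]
            annotations.append(
                AnnotatedCompound(
                    compound_id="",
                    compound_class="glucosinolate",
                    genin=None,
                    sugars=(),
                    acetyl=False,
                    neutral_mass=float(target.mass),
                    rt=float(row["rt"]),
                    adducts={"[M-H]-": row["feature_id"]},
                    name=target.name,
                )
            )

    # unknown candidates: unmatched, non-fragment parents with enough
    # co-eluting diagnostic fragments
    rt = uf["rt"].to_numpy()
    for i in range(len(uf)):
        if matched[i] or is_diag[i]:
            continue
        co = (np.abs(rt - rt[i]) <= rt_tol) & is_diag
        n_diag_coeluting = 0
        for d in diag:
            if np.any(co & (np.abs(mz - d) <= mz_tol)):
                n_diag_coeluting += 1
        if n_diag_coeluting >= min_diag:
            row = uf.iloc[i]
            annotations.append(
                AnnotatedCompound(
                    compound_id="",
                    compound_class="glucosinolate",
                    genin=None,
                    sugars=(),
                    acetyl=False,
                    neutral_mass=float(neutral_from_mh_neg(row["mz"])),
                    rt=float(row["rt"]),
                    adducts={"[M-H]-": row["feature_id"]},
                    name="unknown glucosinolate candidate",
                )
            )

    _assign_isomer_indices(annotations, mass_tol=2 * mz_tol, rt_tol=rt_tol)
    annotations.sort(key=lambda a: (a.neutral_mass, a.rt))
    for a in annotations:
        suffix = f"-iso{a.isomer_index}" if a.isomer_index > 1 else ""
        a.compound_id = f"gls:{a.name}:m{a.neutral_mass:.4f}{suffix}"
    return annotations


def quantify_compounds(features: pd.DataFrame, annotations) -> pd.DataFrame:
    """Per-sample compound intensities from annotated adducts.

    For each cardenolide, the adduct ([M+H]+ or [M+Na]+) with the larger
    intensity summed across all samples is selected globally and reported per
    sample; glucosinolates always use [M-H]-. Samples lacking the selected
    adduct report 0. Returns a samples x compounds DataFrame.
    """
    validate_features(features)
    samples = sorted(features["sample_id"].unique())
    totals = features.groupby("feature_id")["intensity"].sum()
    per_sample = features.pivot_table(
        index="sample_id", columns="feature_id", values="intensity", aggfunc="sum"
    )
    out = pd.DataFrame(0.0, index=pd.Index(samples, name="sample_id"), columns=[])
    for a in annotations:
        for fid in a.adducts.values():
            if fid not in totals.index:
                raise ConsistencyError(
                    f"annotation {a.compound_id} references missing feature {fid}"
                )
        if a.compound_class == "glucosinolate":
            fid = a.adducts["[M-H]-"]
        else:
            # global adduct selection by total intensity; tie prefers [M+H]+
            ranked = sorted(
                a.adducts.items(),
                key=lambda kv: (-totals[kv[1]], kv[0] != "[M+H]+"),
            )
            fid = ranked[0][1]
        col = (
            per_sample[fid].reindex(out.index).fillna(0.0)
            if fid in per_sample.columns
            else pd.Series(0.0, index=out.index)
        )
        out[a.compound_id] = col
    return out
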