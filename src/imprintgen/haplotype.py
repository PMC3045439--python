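"""Two-SNP haplotype extension of the imprinting design.

Two linked SNPs ``A``/``a`` and ``B``/``b`` form four haplotypes AB, Ab, aB,
ab with population frequencies summing to one.  One haplotype is designated
the *risk* haplotype H; the remaining three are pooled as non-risk.  The
maternal/paternal pair of risk vs non-risk haplotypes defines four composite
diplotypes (HH, H|non, non|H, non|non) whose genotypic values carry
haplotype-level additive, dominance and imprinting effects, exactly
mirroring the single-SNP configuration model.

Estimation is two-stage.  Stage 1 estimates the haplotype frequencies and
the recombination fraction ``r`` from genotypes alone, by an exact EM over
the latent ordered diplotypes of every family member: founder diplotypes are
Hardy-Weinberg products of haplotype frequencies, transmitted gametes
recombine with fraction ``r`` in doubly heterozygous parents, and the
E-step sums over all ordered-diplotype assignments of an extended family
(grandparents, sons, wives, grandchildren), so a parent's phase is informed
both by the population frequencies (the classic double-heterozygote
proportion p_AB p_ab / (p_AB p_ab + p_Ab p_aB)) and by the segregation of
its offspring.  The M-step counts expected founder haplotypes and the
expected fraction of recombinant gametes among informative (double
heterozygote) meioses.  Stage 2 plugs the estimates in as per-subject
composite-diplotype priors and runs the same normal-mixture EM as the
single-SNP model, per generation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .family_model import GenerationParams
from .pedigree import PedigreeError, ThreeGenDataset
from .snp_em import FitResult, em_fit

__all__ = [
    "HAPLOTYPES",
    "HaplotypeSystem",
    "HaplotypeFreqFit",
    "RiskSelection",
    "gamete_distribution",
    "transmission_matrix",
    "double_het_phase_weight",
    "diplotype_candidates",
    "genotype_strings",
    "composite_class",
    "offspring_genotype_distribution",
    "em_haplotype_frequencies",
    "diplotype_posteriors",
    "composite_blocks",
    "fit_composite_diplotype_effects",
    "select_risk_haplotype",
]

#: Haplotype order used everywhere; index bit 1 is the a-locus allele
#: (0 = A), bit 0 the b-locus allele (0 = B).
HAPLOTYPES = ("AB", "Ab", "aB", "ab")

_HAP_INDEX = {h: k for k, h in enumerate(HAPLOTYPES)}

SNP1_GENOTYPES = ("AA", "Aa", "aa")
SNP2_GENOTYPES = ("BB", "Bb", "bb")


@dataclass(frozen=True)
class HaplotypeSystem:
    """Haplotype frequencies, linkage and composite-diplotype effects."""

    frequencies: tuple
    r: float
    risk_haplotype: str = "AB"
    params_parental: GenerationParams | None = None
    params_offspring: GenerationParams | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must be 4 non-negative values summing to 1")
        if not 0.0 <= self.r <= 0.5:
            raise ValueError("recombination fraction must be in [0, 0.5]")
        if self.risk_haplotype not in HAPLOTYPES:
            raise ValueError(f"risk haplotype must be one of {HAPLOTYPES}")


@dataclass
class HaplotypeFreqFit:
    """EM estimates of haplotype frequencies and recombination fraction."""

    frequencies: np.ndarray
    r: float
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray


@dataclass
class RiskSelection:
    """Risk-haplotype choice by maximum joint likelihood over the 4 candidates."""

    risk_haplotype: str
    logliks: dict
    fits: dict
    frequencies: np.ndarray
    r: float


# ---------------------------------------------------------------------------
# Elementary transmission machinery
# ---------------------------------------------------------------------------


def _recombinants(h1: int, h2: int) -> tuple:
    return (h1 & 2) | (h2 & 1), (h2 & 2) | (h1 & 1)


def transmission_matrix(r: float) -> np.ndarray:
    """(16, 4) gamete probabilities per ordered diplotype ``4*hm + hp``.

    Parental haplotypes each carry (1-r)/2 and the two locus-swapped
    recombinants r/2; for parents heterozygous at most one locus these
    coincide, so only double heterozygotes depend on ``r``.
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5]")
    T = np.zeros((16, 4))
    for h1 in range(4):
        for h2 in range(4):
            d = 4 * h1 + h2
            r1, r2 = _recombinants(h1, h2)
            T[d, h1] += (1 - r) / 2
            T[d, h2] += (1 - r) / 2
            T[d, r1] += r / 2
            T[d, r2] += r / 2
    return T


#: Per (diplotype, gamete): is this gamete a recombinant of an informative
#: (doubly heterozygous) parent?  And per diplotype: is the parent informative?
_INF = np.array([1 if (d // 4) ^ (d % 4) == 3 else 0 for d in range(16)], dtype=float)
_REC = np.zeros((16, 4))
for _d in range(16):
    if _INF[_d]:
        for _g in range(4):
            _REC[_d, _g] = 0.0 if _g in (_d // 4, _d % 4) else 1.0


def _parse_diplotype(diplotype) -> tuple:
    if isinstance(diplotype, str):
        parts = diplotype.replace("/", "|").split("|")
    else:
        parts = list(diplotype)
    if len(parts) != 2 or any(p not in HAPLOTYPES for p in parts):
        raise ValueError(f"invalid diplotype {diplotype!r}")
    return _HAP_INDEX[parts[0]], _HAP_INDEX[parts[1]]


def gamete_distribution(diplotype, r: float) -> dict:
    """Gamete haplotype distribution of one parent, e.g. ``"AB|ab"``."""
    h1, h2 = _parse_diplotype(diplotype)
    T = transmission_matrix(r)
    return {HAPLOTYPES[g]: float(T[4 * h1 + h2, g]) for g in range(4)}


def double_het_phase_weight(freqs) -> float:
    """Population proportion of the AB/ab phase among double heterozygotes."""
    f = _as_freq_array(freqs)
    num = f[0] * f[3]
    den = num + f[1] * f[2]
    if den == 0.0:
        raise ValueError("both phase products are zero; phase weight undefined")
    return float(num / den)


def _as_freq_array(freqs) -> np.ndarray:
    if isinstance(freqs, dict):
        f = np.array([freqs[h] for h in HAPLOTYPES], dtype=float)
    else:
        f = np.asarray(freqs, dtype=float)
    if f.shape != (4,) or np.any(f < 0):
        raise ValueError("frequencies must be 4 non-negative values")
    return f


def diplotype_candidates(g1: str, g2: str) -> list:
    """Ordered (maternal, paternal) haplotype pairs consistent with a genotype."""
    if g1 not in SNP1_GENOTYPES or g2 not in SNP2_GENOTYPES:
        raise ValueError(f"invalid two-SNP genotype ({g1!r}, {g2!r})")
    a = [0 if ch == "A" else 1 for ch in g1]
    b = [0 if ch == "B" else 1 for ch in g2]
    cands = set()
    for am, ap in ((a[0], a[1]), (a[1], a[0])):
        for bm, bp in ((b[0], b[1]), (b[1], b[0])):
            cands.add(((am << 1) | bm, (ap << 1) | bp))
    return sorted(cands)


def genotype_strings(diplotype) -> tuple:
    """Observable unordered genotypes (snp1, snp2) of an ordered diplotype."""
    hm, hp = diplotype
    g1 = "".join(sorted(("A" if hm < 2 else "a", "A" if hp < 2 else "a")))
    g2 = "".join(sorted(("B" if hm % 2 == 0 else "b", "B" if hp % 2 == 0 else "b")))
    return g1, g2


def composite_class(diplotype, risk: int) -> int:
    """Composite-diplotype index in configuration order: HH, H|non, non|H, non|non."""
    hm, hp = diplotype
    if hm == risk and hp == risk:
        return 0
    if hm == risk:
        return 1
    if hp == risk:
        return 2
    return 3


def offspring_genotype_distribution(mother_genotype, father_genotype, freqs, r) -> dict:
    """Offspring two-SNP genotype distribution for one parental combination.

    Parents' phases are weighted by population diplotype frequencies (the
    double-heterozygote phase proportion emerges automatically); gametes
    follow :func:`gamete_distribution`.  Regenerates, for any of the 81
    parental genotype combinations, the offspring columns of the design's
    transmission tables.
    """
    f = _as_freq_array(freqs)
    T = transmission_matrix(r)

    def phase_dist(geno):
        cands = diplotype_candidates(*geno)
        w = np.array([f[hm] * f[hp] for hm, hp in cands])
        if w.sum() == 0:
            raise ValueError(f"genotype {geno} impossible under given frequencies")
        return cands, w / w.sum()

    mc, mw = phase_dist(mother_genotype)
    fc, fw = phase_dist(father_genotype)
    out: dict = {}
    for (md, wm) in zip(mc, mw):
        gm_dist = T[4 * md[0] + md[1]]
        for (fd, wf) in zip(fc, fw):
            gf_dist = T[4 * fd[0] + fd[1]]
            for hm in range(4):
                if gm_dist[hm] == 0:
                    continue
                for hp in range(4):
                    if gf_dist[hp] == 0:
                        continue
                    key = genotype_strings((hm, hp))
                    out[key] = out.get(key, 0.0) + wm * wf * gm_dist[hm] * gf_dist[hp]
    return out


# ---------------------------------------------------------------------------
# Dataset structure for the family EM
# ---------------------------------------------------------------------------


@dataclass
class _Branch:
    """Per-son arrays within a family group (one second-generation family)."""

    son_c: np.ndarray      # (F, 4) candidate diplotype index
    son_m: np.ndarray      # (F, 4) candidate mask
    son_ids: np.ndarray    # (F,) subject ids
    wife_c: np.ndarray | None
    wife_m: np.ndarray | None
    wife_ids: np.ndarray | None
    child_c: list          # per child: (F, 4)
    child_m: list
    child_ids: list        # per child: (F,)


@dataclass
class _Structure:
    groups: list           # list of (gf_c, gf_m, gm_c, gm_m, gf_ids, gm_ids, [branches])
    lone_c: np.ndarray     # (L, 4) candidates of founders outside any unit
    lone_m: np.ndarray
    n_founders: int


def _pad_candidates(genos) -> tuple:
    """Stack per-subject candidate lists into (n, 4) index + mask arrays."""
    c = np.zeros((len(genos), 4), dtype=int)
    m = np.zeros((len(genos), 4))
    for i, (g1, g2) in enumerate(genos):
        cands = diplotype_candidates(g1, g2)
        for j, (hm, hp) in enumerate(cands):
            c[i, j] = 4 * hm + hp
            m[i, j] = 1.0
    return c, m


def _build_structure(data: ThreeGenDataset) -> _Structure:
    if data.n_snps < 2:
        raise ValueError("haplotype model requires two genotype columns")
    df = data.subjects
    by_id = df.set_index("subject_id")
    used = set()

    fam_units = []
    for fam, fdf in df.groupby("family_id", sort=True):
        gfr = fdf[fdf["role"] == "grandfather"]
        gmr = fdf[fdf["role"] == "grandmother"]
        sons = fdf[fdf["role"] == "father"].sort_values("subject_id")
        if len(gfr) != 1 or len(gmr) != 1:
            raise PedigreeError(f"family {fam} must have one grandfather and one grandmother")
        branches = []
        for son in sons.itertuples():
            kids = df[(df["father_id"] == son.subject_id)].sort_values("subject_id")
            wife_id = None
            if len(kids):
                wids = kids["mother_id"].unique()
                if len(wids) != 1:
                    raise PedigreeError(f"father {son.subject_id} has children by several mothers")
                wife_id = wids[0]
            branches.append((son, wife_id, kids))
            used.add(son.subject_id)
            if wife_id is not None:
                used.add(wife_id)
            used.update(kids["subject_id"])
        fam_units.append((gfr.iloc[0], gmr.iloc[0], branches))
        used.add(gfr.iloc[0]["subject_id"])
        used.add(gmr.iloc[0]["subject_id"])

    # group families with identical branch shapes so arrays stack
    shape_groups: dict = {}
    for gf, gm, branches in fam_units:
        key = tuple((len(kids), wife_id is not None) for _, wife_id, kids in branches)
        shape_groups.setdefault(key, []).append((gf, gm, branches))

    groups = []
    n_founders = 0
    for key, fams in shape_groups.items():
        gf_c, gf_m = _pad_candidates([(f[0]["snp1"], f[0]["snp2"]) for f in fams])
        gm_c, gm_m = _pad_candidates([(f[1]["snp1"], f[1]["snp2"]) for f in fams])
        gf_ids = np.array([f[0]["subject_id"] for f in fams])
        gm_ids = np.array([f[1]["subject_id"] for f in fams])
        n_founders += 2 * len(fams)
        branches = []
        for b, (n_kids, has_wife) in enumerate(key):
            sons = [f[2][b][0] for f in fams]
            son_c, son_m = _pad_candidates([(s.snp1, s.snp2) for s in sons])
            son_ids = np.array([s.subject_id for s in sons])
            if has_wife:
                wives = [by_id.loc[f[2][b][1]] for f in fams]
                wife_c, wife_m = _pad_candidates([(w["snp1"], w["snp2"]) for w in wives])
                wife_ids = np.array([f[2][b][1] for f in fams])
                n_founders += len(fams)
            else:
                wife_c = wife_m = wife_ids = None
            child_c, child_m, child_ids = [], [], []
            for c in range(n_kids):
                kids = [f[2][b][2].iloc[c] for f in fams]
                cc, cm = _pad_candidates([(k["snp1"], k["snp2"]) for k in kids])
                child_c.append(cc)
                child_m.append(cm)
                child_ids.append(np.array([k["subject_id"] for k in kids]))
            branches.append(
                _Branch(son_c, son_m, son_ids, wife_c, wife_m, wife_ids,
                        child_c, child_m, child_ids)
            )
        groups.append((gf_c, gf_m, gm_c, gm_m, gf_ids, gm_ids, branches))

    lone = df[df["role"].isin(("grandfather", "grandmother", "mother"))
              & ~df["subject_id"].isin(used)]
    lone_c, lone_m = _pad_candidates(list(zip(lone["snp1"], lone["snp2"])))
    n_founders += len(lone)
    return _Structure(groups=groups, lone_c=lone_c, lone_m=lone_m, n_founders=n_founders)


# ---------------------------------------------------------------------------
# E-step over extended families
# ---------------------------------------------------------------------------


def _e_step(struct: _Structure, p: np.ndarray, r: float, collect: bool = False):
    """One E-step: log-likelihood, expected founder haplotype counts and
    expected (recombinant, informative) meiosis counts; optionally the
    per-subject posterior over the 16 ordered diplotypes."""
    PF = np.outer(p, p).ravel()
    T = transmission_matrix(r)
    ll = 0.0
    counts = np.zeros(4)
    e_rec = 0.0
    e_inf = 0.0
    post: dict = {} if collect else None

    def add_counts(cand, weight):
        # cand, weight: (..., K); accumulate maternal+paternal haplotypes
        np.add.at(counts, (cand // 4).ravel(), weight.ravel())
        np.add.at(counts, (cand % 4).ravel(), weight.ravel())

    # lone founders
    if len(struct.lone_c):
        pr = PF[struct.lone_c] * struct.lone_m
        lf = pr.sum(axis=1)
        if np.any(lf <= 0):
            raise PedigreeError("founder genotype impossible under current frequencies")
        ll += float(np.log(lf).sum())
        q = pr / lf[:, None]
        add_counts(struct.lone_c, q)

    for gf_c, gf_m, gm_c, gm_m, gf_ids, gm_ids, branches in struct.groups:
        F = gf_c.shape[0]
        prior_gf = PF[gf_c] * gf_m          # (F, A)
        prior_gm = PF[gm_c] * gm_m          # (F, B)

        per_branch = []
        W = prior_gf[:, :, None] * prior_gm[:, None, :]   # (F, A, B)
        for br in branches:
            son_hm = br.son_c // 4
            son_hp = br.son_c % 4
            Pgf = T[gf_c[:, :, None], son_hp[:, None, :]] * br.son_m[:, None, :]  # (F,A,S)
            Pgm = T[gm_c[:, :, None], son_hm[:, None, :]] * br.son_m[:, None, :]  # (F,B,S)
            if br.wife_c is not None:
                pw = PF[br.wife_c] * br.wife_m                                    # (F,Wc)
            else:
                pw = np.ones((F, 1))
            child_terms = []
            Zprod = np.ones((F, pw.shape[1], br.son_c.shape[1]))
            for cc, cm in zip(br.child_c, br.child_m):
                c_hm = cc // 4
                c_hp = cc % 4
                Pw = T[br.wife_c[:, :, None], c_hm[:, None, :]]                   # (F,Wc,K)
                Ps = T[br.son_c[:, :, None], c_hp[:, None, :]]                    # (F,S,K)
                Pc = Pw[:, :, None, :] * Ps[:, None, :, :] * cm[:, None, None, :]  # (F,W,S,K)
                Z = Pc.sum(axis=3)
                child_terms.append((Pc, Z))
                Zprod = Zprod * Z
            BW = pw[:, :, None] * Zprod                                           # (F,W,S)
            U = BW.sum(axis=1)                                                    # (F,S)
            Lb = np.einsum("fas,fbs,fs->fab", Pgf, Pgm, U)                        # (F,A,B)
            per_branch.append((br, Pgf, Pgm, pw, BW, U, Lb, child_terms))
            W = W * Lb

        Lfam = W.sum(axis=(1, 2))
        if np.any(Lfam <= 0):
            bad = np.flatnonzero(Lfam <= 0)
            raise PedigreeError(
                f"zero family likelihood (Mendelian/frequency inconsistency) for "
                f"families of grandfathers {gf_ids[bad][:5].tolist()}"
            )
        ll += float(np.log(Lfam).sum())
        Q = W / Lfam[:, None, None]

        add_counts(gf_c, Q.sum(axis=2))
        add_counts(gm_c, Q.sum(axis=1))
        if collect:
            _record_post(post, gf_ids, gf_c, Q.sum(axis=2))
            _record_post(post, gm_ids, gm_c, Q.sum(axis=1))

        for br, Pgf, Pgm, pw, BW, U, Lb, child_terms in per_branch:
            with np.errstate(invalid="ignore", divide="ignore"):
                Qcond = np.where(Lb > 0, Q / np.where(Lb > 0, Lb, 1.0), 0.0)
            Vs = np.einsum("fab,fas,fbs->fs", Qcond, Pgf, Pgm)                    # (F,S)
            J = BW * Vs[:, None, :]                                               # (F,W,S)

            son_hm = br.son_c // 4
            son_hp = br.son_c % 4
            # meioses into the son
            Msb = np.einsum("fab,fas->fbs", Qcond, Pgf) * Pgm * U[:, None, :]     # (F,B,S)
            e_rec += float((Msb * _REC[gm_c[:, :, None], son_hm[:, None, :]]).sum())
            e_inf += float((Msb * _INF[gm_c][:, :, None]).sum())
            Mas = np.einsum("fab,fbs->fas", Qcond, Pgm) * Pgf * U[:, None, :]     # (F,A,S)
            e_rec += float((Mas * _REC[gf_c[:, :, None], son_hp[:, None, :]]).sum())
            e_inf += float((Mas * _INF[gf_c][:, :, None]).sum())

            if br.wife_c is not None:
                add_counts(br.wife_c, J.sum(axis=2))
                if collect:
                    _record_post(post, br.wife_ids, br.wife_c, J.sum(axis=2))
            if collect:
                _record_post(post, br.son_ids, br.son_c, J.sum(axis=1))

            for (Pc, Z), cc, cm, cids in zip(child_terms, br.child_c, br.child_m, br.child_ids):
                with np.errstate(invalid="ignore", divide="ignore"):
                    H = np.where(Z[:, :, :, None] > 0, (J / np.where(Z > 0, Z, 1.0))[:, :, :, None] * Pc, 0.0)
                c_hm = cc // 4
                c_hp = cc % 4
                RECw = _REC[br.wife_c[:, :, None], c_hm[:, None, :]]              # (F,W,K)
                RECs = _REC[br.son_c[:, :, None], c_hp[:, None, :]]               # (F,S,K)
                e_rec += float(np.einsum("fwsk,fwk->", H, RECw))
                e_rec += float(np.einsum("fwsk,fsk->", H, RECs))
                e_inf += float((J * _INF[br.wife_c][:, :, None]).sum())
                e_inf += float((J * _INF[br.son_c][:, None, :]).sum())
                if collect:
                    _record_post(post, cids, cc, H.sum(axis=(1, 2)))

    return ll, counts, e_rec, e_inf, post


def _record_post(post: dict, ids, cand, weight) -> None:
    for i, sid in enumerate(ids):
        v = post.setdefault(sid, np.zeros(16))
        np.add.at(v, cand[i], weight[i])


# ---------------------------------------------------------------------------
# EM driver and effect fits
# ---------------------------------------------------------------------------


def _init_frequencies(data: ThreeGenDataset) -> np.ndarray:
    founders = data.founders()
    c1 = founders["snp1"].value_counts()
    c2 = founders["snp2"].value_counts()
    n = len(founders)
    pA = (2 * c1.get("AA", 0) + c1.get("Aa", 0)) / (2 * n)
    pB = (2 * c2.get("BB", 0) + c2.get("Bb", 0)) / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        warnings.warn("monomorphic SNP: haplotype frequencies are degenerate", stacklevel=2)
    est = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    return 0.9 * est + 0.1 * 0.25  # keep all phases reachable at the start


def em_haplotype_frequencies(
    data: ThreeGenDataset,
    init=None,
    r_init: float = 0.25,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> HaplotypeFreqFit:
    """EM estimation of (haplotype frequencies, recombination fraction).

    With no double heterozygotes the E-step weights are degenerate and the
    first M-step already performs closed-form counting.  The ``r`` update is
    the expected recombinant proportion among informative meioses, kept in
    [0, 0.5].
    """
    struct = _build_structure(data)
    p = _as_freq_array(init) if init is not None else _init_frequencies(data)
    p = p / p.sum()
    r = float(r_init)
    trace = []
    converged = False
    n_iter = 0
    for it in range(max_iter + 1):
        ll, cnt, e_rec, e_inf, _ = _e_step(struct, p, r)
        trace.append(ll)
        if it > 0 and abs(ll - trace[-2]) < tol:
            converged = True
            break
        if it == max_iter:
            break
        p = cnt / cnt.sum()
        if e_inf > 1e-12:
            r = float(np.clip(e_rec / e_inf, 0.0, 0.5))
        n_iter = it + 1
    if not converged:
        warnings.warn("haplotype EM did not converge; best iterate returned", stacklevel=2)
    return HaplotypeFreqFit(
        frequencies=p, r=r, loglik=trace[-1], n_iter=n_iter,
        converged=converged, loglik_trace=np.asarray(trace),
    )


def diplotype_posteriors(data: ThreeGenDataset, freqs, r: float) -> dict:
    """Per-subject posterior over the 16 ordered diplotypes given all genotypes."""
    struct = _build_structure(data)
    _, _, _, _, post = _e_step(struct, _as_freq_array(freqs), float(r), collect=True)
    return post


def _risk_index(risk) -> int:
    if isinstance(risk, str):
        return _HAP_INDEX[risk]
    return int(risk)


_CLASS_OF = {}
for _hm in range(4):
    for _hp in range(4):
        for _rk in range(4):
            _CLASS_OF[(4 * _hm + _hp, _rk)] = composite_class((_hm, _hp), _rk)

_CLASS_MATRIX = np.zeros((4, 16), dtype=int)  # [risk, diplotype] -> class
for (_d, _rk), _cl in _CLASS_OF.items():
    _CLASS_MATRIX[_rk, _d] = _cl


def composite_blocks(data: ThreeGenDataset, freqs, r, risk) -> dict:
    """Phenotype vectors and composite-diplotype priors per generation."""
    rk = _risk_index(risk)
    post = diplotype_posteriors(data, freqs, r)
    blocks = {}
    for key, role in (("parental", "father"), ("offspring", "child")):
        rows = data.rows(role)
        rows = rows[rows["phenotype"].notna()]
        y = rows["phenotype"].to_numpy(float)
        P = np.zeros((len(rows), 4))
        for i, sid in enumerate(rows["subject_id"]):
            p16 = post[sid]
            for d in range(16):
                if p16[d] > 0:
                    P[i, _CLASS_MATRIX[rk, d]] += p16[d]
        P = P / P.sum(axis=1, keepdims=True)
        blocks[key] = (y, P)
    return blocks


def fit_composite_diplotype_effects(
    data: ThreeGenDataset, freqs, r, risk, constraints=(), **em_opts
) -> FitResult:
    """Normal-mixture EM for (mu, a, d, i, sigma2) per generation on composite
    diplotypes of the chosen risk haplotype; supports the same constraint
    vocabulary as the single-SNP fit (ties enable haplotype-level
    transgenerational tests)."""
    rk = _risk_index(risk)
    f = _as_freq_array(freqs)
    if f[rk] < 1e-6:
        warnings.warn("risk haplotype has ~zero frequency; contrasts inestimable", stacklevel=2)
    blocks = composite_blocks(data, f, r, rk)
    fit = em_fit(blocks, constraints=tuple(constraints), **em_opts)
    fit.meta["risk_haplotype"] = HAPLOTYPES[rk]
    return fit


def select_risk_haplotype(data: ThreeGenDataset, freqs=None, r=None, **em_opts) -> RiskSelection:
    """Exhaustive single-risk-haplotype choice by maximum joint log-likelihood.

    All four candidate fits are returned so near-ties are visible; exact ties
    break toward the more frequent haplotype.
    """
    if freqs is None or r is None:
        stage1 = em_haplotype_frequencies(data)
        freqs, r = stage1.frequencies, stage1.r
    f = _as_freq_array(freqs)
    fits = {}
    logliks = {}
    for h in HAPLOTYPES:
        fits[h] = fit_composite_diplotype_effects(data, f, r, h, **em_opts)
        logliks[h] = fits[h].loglik
    best = max(HAPLOTYPES, key=lambda h: (round(logliks[h], 9), f[_HAP_INDEX[h]]))
    return RiskSelection(risk_haplotype=best, logliks=logliks, fits=fits,
                         frequencies=f, r=float(r))
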