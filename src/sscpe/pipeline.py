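"""End-to-end orchestration: structures + MSA -> site-specific models.

The pipeline mirrors the published workflow: each structure's sequence is
aligned against the MSA and discarded below 50% identity; structures that
are predicted unstable on their own sequence, or that stabilize too few
sequences, are discarded; sequences insufficiently stabilized by the
retained structures are dropped; all-gap columns are removed; per-structure
fitness matrices are combined site-wise with weights proportional to the
number of sequences each structure stabilizes.  Sites not covered by any
structure get zero fitness and are described by the global frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AA
from .enm import build_torsional_enm
from .mutation import build_effect_table
from .params import ENMParameters, MutationParameters, StabilityParameters
from .profiles import (
    EPSILON,
    MODEL_CHANNELS,
    MSAProfile,
    SiteProfileSet,
    fit_lambda,
    fit_lambdas_joint,
    mf_fitness,
    regularization_path,
    stationary_distribution,
    fit_global_frequencies,
    wt_fitness,
)
from .stability import ContactStatistics, DeltaGEvaluator, delta_g
from .structure import ProteinStructure, build_contact_map

logger = logging.getLogger(__name__)


def read_fasta(path: str) -> tuple[list[str], list[str]]:
    """(names, aligned sequences); gaps are '-' ('.' normalized to '-')."""
    from Bio import SeqIO

    names, seqs = [], []
    for rec in SeqIO.parse(path, "fasta"):
        names.append(rec.id)
        seqs.append(str(rec.seq).upper().replace(".", "-"))
    if not names:
        raise ValueError(f"no sequences in {path!r}")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("alignment rows have unequal lengths")
    return names, seqs


def write_fasta(names: list[str], seqs: list[str], path: str) -> None:
    with open(path, "w") as fh:
        for n, s in zip(names, seqs):
            fh.write(f">{n}\n{s}\n")


# ---------------------------------------------------------------------------
# structure-MSA matching and filters
# ---------------------------------------------------------------------------

@dataclass
class StructureMatch:
    best_sequence: int
    identity: float
    column_of_site: np.ndarray      # MSA column of every structure site (-1 if unaligned)
    accepted: bool


def _global_align(a: str, b: str):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner.align(a, b)[0]


def match_structure_to_msa(
    structure_seq: str,
    msa_sequences: list[str],
    min_identity: float = 0.5,
) -> StructureMatch:
    """Align the structure's sequence to every MSA row; keep the best match.

    Identity is the fraction of matching residues over aligned (non-gap)
    positions of a global alignment with BLOSUM62 and affine gap penalties
    (-11 open, -1 extend).  Below ``min_identity`` the structure is rejected.
    """
    best = (-1.0, None, None)
    for s_idx, row in enumerate(msa_sequences):
        ungapped = row.replace("-", "")
        if not ungapped:
            continue
        aln = _global_align(structure_seq, ungapped)
        pairs = [
            (qi, ti)
            for (qs, qe), (ts, te) in zip(*aln.aligned)
            for qi, ti in zip(range(qs, qe), range(ts, te))
        ]
        if not pairs:
            continue
        ident = sum(structure_seq[qi] == ungapped[ti] for qi, ti in pairs) / len(pairs)
        if ident > best[0]:
            best = (ident, s_idx, pairs)
    identity, s_idx, pairs = best
    if s_idx is None:
        return StructureMatch(-1, 0.0, np.full(len(structure_seq), -1), False)
    row = msa_sequences[s_idx]
    col_of_respos = [i for i, c in enumerate(row) if c != "-"]
    col_of_site = np.full(len(structure_seq), -1, dtype=np.int64)
    for qi, ti in pairs:
        col_of_site[qi] = col_of_respos[ti]
    return StructureMatch(s_idx, identity, col_of_site, identity >= min_identity)


def thread_sequence(
    structure: ProteinStructure, match: StructureMatch, msa_row: str
) -> np.ndarray:
    """Amino-acid indices of an MSA sequence threaded on the structure.

    Structure sites whose MSA column carries a gap (or that are unaligned)
    keep the structure's own residue, so contact sums stay defined.
    """
    idx = np.array([AA_INDEX[a] for a in structure.sequence], dtype=np.int64)
    for site, col in enumerate(match.column_of_site):
        if col >= 0:
            aa = msa_row[col]
            if aa in AA_INDEX:
                idx[site] = AA_INDEX[aa]
    return idx


@dataclass
class StructureSequenceFit:
    """Stability cross-table between structures and MSA sequences."""

    delta_g: np.ndarray          # (n_struct, n_seq)
    f_ps: np.ndarray             # (n_struct, n_seq) = 1/(1+exp(delta_g))
    own_delta_g: np.ndarray      # (n_struct,) on the structure's own sequence
    matches: list[StructureMatch]


def compute_fits(
    structures: list[ProteinStructure],
    matches: list[StructureMatch],
    msa_sequences: list[str],
    cs: ContactStatistics | None,
    sp: StabilityParameters | None = None,
    use_misfold: bool = True,
) -> StructureSequenceFit:
    sp = sp or StabilityParameters()
    n_p, n_s = len(structures), len(msa_sequences)
    dg = np.zeros((n_p, n_s))
    own = np.zeros(n_p)
    for p, (struct, match) in enumerate(zip(structures, matches)):
        cm = build_contact_map(struct, "stability")
        own[p] = delta_g(struct.sequence, cm, cs, sp, use_misfold=use_misfold).delta_g
        for s_i, row in enumerate(msa_sequences):
            idx = thread_sequence(struct, match, row)
            dg[p, s_i] = delta_g(idx, cm, cs, sp, use_misfold=use_misfold).delta_g
    f_ps = 1.0 / (1.0 + np.exp(np.clip(dg, -500, 500)))
    return StructureSequenceFit(delta_g=dg, f_ps=f_ps, own_delta_g=own, matches=matches)


def filter_structures(fits: StructureSequenceFit, n_seq: int) -> list[int]:
    """Retain structures that are stable (own Delta G < 0) and stabilize at
    least min(4.5, 0.45 * n_seq) sequences."""
    threshold = min(4.5, 0.45 * n_seq)
    retained = []
    for p in range(fits.f_ps.shape[0]):
        if not fits.matches[p].accepted:
            logger.info("structure %d rejected: identity %.2f below 0.5",
                        p, fits.matches[p].identity)
            continue
        if fits.own_delta_g[p] >= 0:
            logger.info("structure %d rejected: predicted unstable (dG=%.2f)",
                        p, fits.own_delta_g[p])
            continue
        coverage = float(fits.f_ps[p].sum())
        if coverage < threshold:
            logger.info("structure %d rejected: stabilizes %.2f < %.2f sequences",
                        p, coverage, threshold)
            continue
        retained.append(p)
    if not retained:
        raise RuntimeError(
            "all structures were rejected (low identity, instability or "
            "insufficient sequence coverage)"
        )
    return retained


def filter_sequences(
    fits: StructureSequenceFit,
    retained_structures: list[int],
    names: list[str],
    seqs: list[str],
    min_score: float = 0.9,
) -> tuple[list[str], list[str], np.ndarray]:
    """Drop sequences with stability score below ``min_score``, then all-gap
    columns; returns (names, sequences, old->new column map)."""
    score = fits.f_ps[retained_structures].sum(axis=0)
    keep = [i for i in range(len(seqs)) if score[i] >= min_score]
    if not keep:
        raise RuntimeError("no sequence passes the stability-score filter")
    for i in range(len(seqs)):
        if i not in keep:
            logger.info("sequence %s dropped: stability score %.2f < %.2f",
                        names[i], score[i], min_score)
    kept_seqs = [seqs[i] for i in keep]
    n_col = len(kept_seqs[0])
    nonempty = [c for c in range(n_col)
                if any(s[c] != "-" for s in kept_seqs)]
    col_map = np.full(n_col, -1, dtype=np.int64)
    for new, old in enumerate(nonempty):
        col_map[old] = new
    out_seqs = ["".join(s[c] for c in nonempty) for s in kept_seqs]
    return [names[i] for i in keep], out_seqs, col_map


def combine_structure_fitness(
    phis: list[np.ndarray],
    coverages: list[np.ndarray],
    weights: np.ndarray,
    n_columns: int,
) -> np.ndarray:
    """Weighted site-wise average of per-structure fitness matrices.

    ``phis[p]`` is (L_p-columns, 20) already placed on MSA columns via
    ``coverages[p]`` (boolean over columns); uncovered columns stay zero.
    """
    phi = np.zeros((n_columns, N_AA))
    wsum = np.zeros(n_columns)
    for phi_p, cov, w in zip(phis, coverages, weights):
        phi[cov] += w * phi_p[cov]
        wsum[cov] += w
    covered = wsum > 0
    phi[covered] /= wsum[covered, None]
    return phi


# ---------------------------------------------------------------------------
# full profile computation
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    model: str
    profiles: SiteProfileSet
    msa_profile: MSAProfile
    names: list[str]
    sequences: list[str]
    covered: np.ndarray             # boolean over retained columns
    reg_info: dict = field(default_factory=dict)


def _phi_matrices_for_structure(
    struct: ProteinStructure,
    cs: ContactStatistics | None,
    sp: StabilityParameters,
    mp: MutationParameters,
    enm_p: ENMParameters,
    need_stab: set[str],
    need_str: set[str],
    use_misfold: bool = True,
):
    """Per-structure fitness building blocks keyed by channel name."""
    out: dict[str, object] = {}
    cm_stab = build_contact_map(struct, "stability")
    if "WT" in need_stab:
        ev = DeltaGEvaluator(struct.sequence, cm_stab, cs, sp, use_misfold=use_misfold)
        out["WT"] = wt_fitness(ev)
    if "MF" in need_stab:
        out["MF"] = mf_fitness(struct.sequence, cm_stab, cs, sp,
                               use_misfold=use_misfold)
    if need_str:
        cm_enm = build_contact_map(struct, "enm", cutoff=enm_p.cutoff)
        mb = build_torsional_enm(struct, cm_enm, enm_p)
        out["effects"] = build_effect_table(struct, cm_enm, mb, mp, K=enm_p.K)
    return out


def compute_profiles(
    model: str,
    structures: list[ProteinStructure],
    msa_names: list[str],
    msa_seqs: list[str],
    cs: ContactStatistics | None = None,
    sp: StabilityParameters | None = None,
    mp: MutationParameters | None = None,
    enm_p: ENMParameters | None = None,
    use_regularization: bool = True,
    R: float = 0.0,
    criterion: str = "KLsymm",
    epsilon: float = EPSILON,
    use_misfold: bool = True,
) -> PipelineResult:
    """Run the full pipeline for one model name (GLOB, MF, ..., RMSDWT)."""
    sp = sp or StabilityParameters()
    mp = mp or MutationParameters()
    enm_p = enm_p or ENMParameters()
    stab_kind, str_kind = MODEL_CHANNELS[model]

    matches = [match_structure_to_msa(st.sequence, msa_seqs) for st in structures]
    fits = compute_fits(structures, matches, msa_seqs, cs, sp, use_misfold)
    retained = filter_structures(fits, len(msa_seqs))
    names, seqs, col_map = filter_sequences(fits, retained, msa_names, msa_seqs)
    n_columns = len(seqs[0])
    msa_profile = MSAProfile.from_sequences(seqs, epsilon=epsilon)

    weights = fits.f_ps[retained].sum(axis=1)
    weights = weights / weights.sum()

    need_stab = {stab_kind} if stab_kind else set()
    need_str = {str_kind} if str_kind else set()
    phi_stab_parts, str_effect_parts, coverages = [], [], []
    for p in retained:
        struct = structures[p]
        blocks = _phi_matrices_for_structure(
            struct, cs, sp, mp, enm_p, need_stab, need_str, use_misfold
        )
        cols = np.array([col_map[c] if c >= 0 else -1
                         for c in matches[p].column_of_site])
        cov = np.zeros(n_columns, dtype=bool)
        placed_stab = np.zeros((n_columns, N_AA))
        placed_rmsd = np.zeros((n_columns, N_AA))
        placed_de = np.zeros((n_columns, N_AA))
        for site, col in enumerate(cols):
            if col < 0:
                continue
            cov[col] = True
            if stab_kind:
                placed_stab[col] = blocks[stab_kind][site]
            if str_kind:
                placed_rmsd[col] = blocks["effects"].rmsd[site]
                placed_de[col] = blocks["effects"].de[site]
        coverages.append(cov)
        if stab_kind:
            phi_stab_parts.append(placed_stab)
        if str_kind:
            str_effect_parts.append(placed_de if str_kind == "DE" else placed_rmsd)

    covered = np.zeros(n_columns, dtype=bool)
    for cov in coverages:
        covered |= cov

    phi_stab = (
        combine_structure_fitness(phi_stab_parts, coverages, weights, n_columns)
        if stab_kind else None
    )
    # structural deformations are averaged on the deformation scale, then the
    # Lambda-dependent wild-type entries and the sign are applied per column
    str_deform = (
        combine_structure_fitness(str_effect_parts, coverages, weights, n_columns)
        if str_kind else None
    )
    # wild-type amino acid per column (from the highest-weight covering
    # structure): needed to refresh the Lambda-dependent wild-type average
    wt_aa_col = np.full(n_columns, -1, dtype=np.int64)
    if str_kind:
        order = np.argsort(weights)  # ascending: later (heavier) overwrite
        for rank in order:
            p = retained[rank]
            struct = structures[p]
            for site, c in enumerate(matches[p].column_of_site):
                col = col_map[c] if c >= 0 else -1
                if col >= 0:
                    wt_aa_col[col] = AA_INDEX[struct.sequence[site]]

    def phi_fn(lams: tuple[float, float]) -> np.ndarray:
        from .mutation import wild_type_average

        lam_stab, lam_str = lams
        x = np.zeros((n_columns, N_AA))
        if phi_stab is not None:
            x += lam_stab * phi_stab
        if str_deform is not None:
            mat = str_deform.copy()
            for i in np.flatnonzero(wt_aa_col >= 0):
                wt = wt_aa_col[i]
                others = [b for b in range(N_AA) if b != wt]
                mat[i, wt] = wild_type_average(mat[i, others], lam_str)
            x += lam_str * (-mat)
        return x

    reg_info: dict = {}
    if model == "GLOB":
        lam_stab = lam_str = 0.0
    elif stab_kind and str_kind:
        (lam_stab, lam_str), _sc = fit_lambdas_joint(
            phi_fn, msa_profile, criterion, R, epsilon=epsilon
        )
    else:
        channel = 0 if stab_kind else 1
        if use_regularization:
            path = regularization_path(
                phi_fn, msa_profile, criterion, epsilon=epsilon, channel=channel
            )
            lam = path.chosen_lambda
            reg_info = {"chosen_R": path.chosen_R, "R_grid": path.R_grid,
                        "kl_at_R": path.kl_at_R, "cv_at_R": path.cv_at_R}
        else:
            lam, _sc = fit_lambda(
                phi_fn, msa_profile, criterion, R, epsilon=epsilon, channel=channel
            )
        lam_stab, lam_str = (lam, 0.0) if channel == 0 else (0.0, lam)

    x = phi_fn((lam_stab, lam_str))
    p_glob = fit_global_frequencies(x, msa_profile)
    P, Z = stationary_distribution(x, p_glob, epsilon)
    if str_deform is not None:
        x_stab = lam_stab * phi_stab if phi_stab is not None else 0.0
        phi_str_final = (x - x_stab) / lam_str if lam_str > 0 else -str_deform
    else:
        phi_str_final = None
    profiles = SiteProfileSet(
        model=model, P=P, p_glob=p_glob, Z=Z,
        lambda_stab=lam_stab, lambda_str=lam_str,
        phi_stab=phi_stab,
        phi_str=phi_str_final,
        epsilon=epsilon,
    )
    return PipelineResult(
        model=model, profiles=profiles, msa_profile=msa_profile,
        names=names, sequences=seqs, covered=covered, reg_info=reg_info,
    )


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_profiles(result: PipelineResult, path: str) -> None:
    """Per structured column: 20 stationary frequencies (tab separated)."""
    prof = result.profiles
    with open(path, "w") as fh:
        fh.write(f"# model {prof.model}  lambda_stab {prof.lambda_stab:.6g}  "
                 f"lambda_str {prof.lambda_str:.6g}\n")
        fh.write("# p_glob\t" + "\t".join(f"{x:.6f}" for x in prof.p_glob) + "\n")
        fh.write("#col\t" + "\t".join(AMINO_ACIDS) + "\n")
        for i in range(prof.L):
            if result.covered[i]:
                fh.write(f"{i + 1}\t" + "\t".join(f"{x:.6f}" for x in prof.P[i]) + "\n")


def write_rate_profile(path: str, rates_by_option: dict[str, np.ndarray]) -> None:
    """Per-site predicted rates for several exchangeability variants."""
    keys = sorted(rates_by_option)
    L = len(next(iter(rates_by_option.values())))
    with open(path, "w") as fh:
        fh.write("#site\t" + "\t".join(keys) + "\n")
        for i in range(L):
            fh.write(f"{i + 1}\t" +
                     "\t".join(f"{rates_by_option[k][i]:.6f}" for k in keys) + "\n")


def export_partitions(models, out_path: str) -> None:
    """Write the per-site models in a documented text layout.

    Layout per site: a ``site`` line, a ``freqs`` line (20 values), a
    ``scale`` line, and 19 lower-triangle exchangeability rows.  Files are
    deterministic byte-for-byte given the model set.
    """
    with open(out_path, "w") as fh:
        fh.write("# sscpe per-site partition models\n")
        fh.write(f"# options {sorted(models.options.items())}\n")
        for i in range(models.L):
            fh.write(f"site {i + 1}\n")
            fh.write("freqs " + " ".join(f"{x:.10f}" for x in models.P[i]) + "\n")
            fh.write(f"scale {models.scale[i]:.10f}\n")
            for r in range(1, N_AA):
                fh.write(" ".join(f"{models.E[i][r, c]:.10f}" for c in range(r)) + "\n")


def read_partitions(path: str):
    """Round-trip reader for :func:`export_partitions` (validation aid)."""
    sites, freqs, scales, tris = [], [], [], []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    k = 0
    while k < len(lines):
        assert lines[k].startswith("site")
        sites.append(int(lines[k].split()[1]))
        freqs.append([float(x) for x in lines[k + 1].split()[1:]])
        scales.append(float(lines[k + 2].split()[1]))
        tri = []
        for r in range(1, N_AA):
            tri.append([float(x) for x in lines[k + 3 + r - 1].split()])
        tris.append(tri)
        k += 3 + (N_AA - 1)
    L = len(sites)
    E = np.zeros((L, N_AA, N_AA))
    for i, tri in enumerate(tris):
        for r in range(1, N_AA):
            for c in range(r):
                E[i, r, c] = E[i, c, r] = tri[r - 1][c]
    return np.array(freqs), np.array(scales), E
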