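"""Synthetic ground-truth generator for the elutriation analysis.

Generates a universe of genes with phase-level protein expression, isoform
structure, peptide-level evidence, RNA abundances coupled to protein levels
through a Gaussian copula, and annotation/motif structure, such that every
downstream module sees data with the statistical features the analysis
assumes:

* log-normal protein copy numbers spanning many orders of magnitude;
* a small configurable fraction of genes cell-cycle regulated, with a
  configurable mix of peak phases;
* asynchronous samples that are exact cell-count-weighted mixtures of the
  six elutriated fractions (pre-noise);
* multi-isoform genes where one isoform is regulated while another stays
  flat (isoform switching), so gene-level aggregation masks the regulation;
* phosphopeptides with configurable S/T/Y proportions, a subset carrying
  independently regulated site stoichiometry;
* rank correlation between protein and mRNA abundance set by the copula;
* KEN / RxxL degrons injected into coordinated genes, and TFBS / GO-like
  annotation terms enriched in the relevant gene classes.

Everything is driven by a single ``numpy`` Generator so a fixed seed gives
bit-identical outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import (
    PEAK_CLASSES,
    SAMPLES,
    FractionMeta,
    SimulationConfig,
    cell_count_weights,
    composition_matrix,
    fractions_to_frame,
)
from .digestion import LYSC, TRYPSIN_DD, DigestSpec, digest_sequence

# residue frequencies of the human proteome (rounded, renormalized)
_HUMAN_AA = {
    "A": 0.0702, "C": 0.0230, "D": 0.0474, "E": 0.0710, "F": 0.0365,
    "G": 0.0658, "H": 0.0263, "I": 0.0433, "K": 0.0572, "L": 0.0996,
    "M": 0.0213, "N": 0.0359, "P": 0.0631, "Q": 0.0477, "R": 0.0564,
    "S": 0.0833, "T": 0.0536, "V": 0.0597, "W": 0.0122, "Y": 0.0266,
}
AA_LETTERS = np.array(list(_HUMAN_AA))
AA_PROBS = np.array(list(_HUMAN_AA.values()))
AA_PROBS = AA_PROBS / AA_PROBS.sum()


@dataclass
class GroundTruth:
    """Per-gene and per-isoform truth plus the expected measurement surface.

    ``genes``: indexed by gene_id; phase-level gene totals ``x_G1/x_S/x_G2M``
    (per-cell intensity units), regulation flags, peak class, true fraction
    fold, copy number, pre-noise FPKM per pooled sample, histone flag.
    ``isoforms``: indexed by isoform_id; sequence and per-cell phase
    abundance ``a_G1/a_S/a_G2M``.
    ``expected``: isoform x sample matrix of pre-noise per-cell intensities;
    the ASYNC column is exactly the cell-count-weighted mixture of F1..F6.
    """

    config: SimulationConfig
    genes: pd.DataFrame
    isoforms: pd.DataFrame
    expected: pd.DataFrame
    annotations: pd.DataFrame
    fractions: tuple[FractionMeta, ...]

    @property
    def fasta(self) -> dict[str, str]:
        return dict(zip(self.isoforms.index, self.isoforms["sequence"]))

    def gene_expected(self) -> pd.DataFrame:
        """Per-gene expected per-cell intensity per sample (isoform sums)."""
        return self.expected.groupby(self.isoforms["gene_id"]).sum()


# ---------------------------------------------------------------------------
# phase-shape solving


def _fraction_fold(shape: np.ndarray, M: np.ndarray) -> float:
    mixed = M @ shape
    return float(mixed.max() / mixed.min())


def _class_shape(peak_class: str, t: float) -> np.ndarray:
    """Unit phase shape for a peak class at contrast parameter ``t >= 1``.

    For single-phase classes the peak phase is elevated t-fold; for the
    dual-peak class S is depressed (parameter maps t in [1, inf) onto an
    S level in (0, 1])."""
    if peak_class == "G1":
        return np.array([t, 1.0, 1.0])
    if peak_class == "S":
        return np.array([1.0, t, 1.0])
    if peak_class == "G2M":
        return np.array([1.0, 1.0, t])
    if peak_class == "G2M+G1":
        return np.array([1.0, 1.0 / t, 1.0])
    raise ValueError(f"unknown peak class {peak_class!r}")


def max_fraction_fold(peak_class: str, M: np.ndarray) -> float:
    """Supremum of the achievable 6-fraction fold for a peak class given the
    phase-composition matrix (fractions are mixtures, so the phase-level
    contrast is attenuated)."""
    return _fraction_fold(_class_shape(peak_class, 1e9), M)


def solve_phase_shape(peak_class: str, target_fold: float, M: np.ndarray) -> np.ndarray:
    """Phase 3-vector whose fraction-level fold equals ``target_fold``."""
    if target_fold <= 1.0:
        return np.ones(3)
    limit = max_fraction_fold(peak_class, M)
    if target_fold >= limit:
        raise ValueError(
            f"fraction fold {target_fold:.3g} unreachable for class {peak_class} "
            f"(limit {limit:.3g} with this composition matrix)"
        )
    t = brentq(
        lambda u: _fraction_fold(_class_shape(peak_class, u), M) - target_fold,
        1.0 + 1e-12, 1e9, xtol=1e-12, rtol=1e-12,
    )
    return _class_shape(peak_class, t)


def _wiggle_shape(rng: np.random.Generator, amplitude: float) -> np.ndarray:
    """Mild non-flat phase shape for unregulated genes (fold << 2)."""
    shape = np.ones(3)
    shape[rng.integers(0, 3)] += rng.uniform(0.0, amplitude)
    return shape


def _anti_shape(partner: np.ndarray, beta: float = 0.6) -> np.ndarray:
    """Flat-but-anti-phased shape for the non-regulated isoform of a
    discordant gene: isoform switching trades abundance against the
    regulated partner, so the two profiles anti-correlate while the flat
    isoform stays well below the regulation cutoff."""
    s = partner / partner.max()
    shape = 1.0 - beta * (s - s.mean())
    return np.clip(shape, 0.25, None)


# ---------------------------------------------------------------------------
# sequences


def _random_sequences(rng: np.random.Generator, lengths: np.ndarray) -> list[str]:
    total = int(lengths.sum())
    letters = rng.choice(AA_LETTERS, size=total, p=AA_PROBS)
    out, pos = [], 0
    for n in lengths:
        out.append("".join(letters[pos:pos + int(n)]))
        pos += int(n)
    return out


def _inject_motifs(seq: str, rng: np.random.Generator) -> str:
    """Overwrite random interior windows with a KEN box and an RxxL D-box."""
    s = list(seq)
    n = len(s)
    ken_pos = int(rng.integers(5, max(6, n - 10)))
    s[ken_pos:ken_pos + 3] = list("KEN")
    for _ in range(20):  # avoid clobbering the KEN we just placed
        dbox_pos = int(rng.integers(5, max(6, n - 10)))
        if abs(dbox_pos - ken_pos) > 6:
            break
    x1, x2 = rng.choice(AA_LETTERS, size=2)
    s[dbox_pos:dbox_pos + 4] = ["R", str(x1), str(x2), "L"]
    return "".join(s)


# ---------------------------------------------------------------------------
# ground truth


def generate_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Build the gene/isoform/fraction ground truth for a configuration.

    Per-fraction expected per-cell intensity is ``I_f = sum_p pi_fp x_p``
    and the asynchronous expectation is the cell-count-weighted mean of the
    fraction expectations — an exact identity by construction.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    M = composition_matrix(config.fractions)
    w = cell_count_weights(config.fractions)
    async_comp = w @ M  # phase composition of the async mixture
    lo, hi = config.fold_range

    gene_ids = [f"G{i:06d}" for i in range(1, n + 1)]
    copy_number = 10.0 ** rng.normal(config.log_copy_mean, config.log_copy_sd, n)

    regulated = rng.random(n) < config.frac_regulated
    peak_class = np.array([""] * n, dtype=object)
    classes = rng.choice(len(PEAK_CLASSES), size=n, p=config.peak_phase_mix)
    peak_class[regulated] = np.array(PEAK_CLASSES, dtype=object)[classes[regulated]]

    coordinated = np.zeros(n, dtype=bool)
    coordinated[regulated] = rng.random(regulated.sum()) < config.coordinated_rate
    is_histone = rng.random(n) < config.histone_rate

    # isoform counts and abundance shares
    n_iso = rng.choice(np.arange(1, len(config.isoform_rate) + 1),
                       size=n, p=config.isoform_rate)
    multi = (n_iso > 1) & ~regulated
    discordant = multi & (rng.random(n) < config.discordant_rate)
    if config.frac_regulated == 0:
        discordant[:] = False  # a regulation-free universe stays flat everywhere

    # phase shapes: gene-level target fraction folds
    gene_fold_target = np.ones(n)
    for k, cls in enumerate(PEAK_CLASSES):
        mask = regulated & (peak_class == cls)
        if not mask.any():
            continue
        cap = 0.97 * max_fraction_fold(cls, M)
        lo_c, hi_c = min(lo, cap), min(hi, cap)
        gene_fold_target[mask] = rng.uniform(lo_c, hi_c, mask.sum())

    gene_shapes = np.ones((n, 3))
    for i in np.flatnonzero(regulated):
        gene_shapes[i] = solve_phase_shape(peak_class[i], gene_fold_target[i], M)
    for i in np.flatnonzero(~regulated):
        gene_shapes[i] = _wiggle_shape(rng, config.unregulated_wiggle)

    # per-isoform phase abundance (unnormalized), then scale so the async
    # expectation of the gene total equals the drawn copy number
    iso_rows = []          # (isoform_id, gene_idx, share, shape)
    iso_reg_fold = {}      # isoform_id -> regulated isoform target fold
    for i in range(n):
        k = int(n_iso[i])
        shares = rng.dirichlet(np.full(k, 3.0)) if k > 1 else np.array([1.0])
        if discordant[i]:
            # one regulated isoform at a minority share + flat partners:
            # pooled gene-level fold stays below the cutoff (masking)
            f_iso = rng.uniform(4.0, min(6.0, 0.97 * max_fraction_fold("G1", M)))
            cls = str(rng.choice(["G1", "S", "G2M"]))
            f_iso = min(f_iso, 0.97 * max_fraction_fold(cls, M))
            reg_shape = solve_phase_shape(cls, f_iso, M)
            # bound the regulated share by the phase-level amplitude so the
            # pooled gene profile stays clearly below the twofold cutoff
            share_reg = rng.uniform(0.10, 0.80) / (reg_shape.max() - 1.0)
            rest = (1.0 - share_reg) * shares[1:] / shares[1:].sum()
            anti = _anti_shape(reg_shape)
            iso_rows.append((f"{gene_ids[i]}-1", i, share_reg, reg_shape))
            iso_reg_fold[f"{gene_ids[i]}-1"] = f_iso
            for j in range(1, k):
                iso_rows.append((f"{gene_ids[i]}-{j+1}", i, rest[j - 1], anti))
        else:
            for j in range(k):
                iso_rows.append((f"{gene_ids[i]}-{j+1}", i, shares[j], gene_shapes[i]))

    iso_ids = [r[0] for r in iso_rows]
    iso_gene_idx = np.array([r[1] for r in iso_rows])
    iso_u = np.array([r[2] * np.asarray(r[3]) for r in iso_rows])  # n_iso x 3

    # scale: per-gene async expectation -> copy number
    gene_async_u = np.zeros(n)
    np.add.at(gene_async_u, iso_gene_idx, iso_u @ async_comp)
    scale = copy_number / gene_async_u
    iso_a = iso_u * scale[iso_gene_idx][:, None]

    iso_expected_fr = iso_a @ M.T                 # n_iso x 6
    iso_expected_async = iso_a @ async_comp       # exact weighted mixture
    expected = pd.DataFrame(
        np.column_stack([iso_expected_fr, iso_expected_async]),
        index=pd.Index(iso_ids, name="isoform_id"), columns=list(SAMPLES),
    )

    gene_x = np.zeros((n, 3))
    np.add.at(gene_x, iso_gene_idx, iso_a)
    gene_fr = gene_x @ M.T
    gene_fold = gene_fr.max(axis=1) / gene_fr.min(axis=1)

    # --- RNA via Gaussian copula against log protein abundance ------------
    rho_s = config.rna_protein_rho
    rho_z = 2.0 * math.sin(math.pi * rho_s / 6.0)  # Spearman -> Pearson (normal)
    z_prot = (np.log10(copy_number) - config.log_copy_mean) / config.log_copy_sd
    z_rna = rho_z * z_prot + math.sqrt(1.0 - rho_z ** 2) * rng.standard_normal(n)
    fpkm_async = 10.0 ** (config.rna_log_mean + config.rna_log_sd * z_rna)

    rna_shape = np.ones((n, 3))
    coord_idx = np.flatnonzero(coordinated)
    if coord_idx.size:
        rna_fold = rng.uniform(max(1.6, config.rna_regulated_fold * 1.05), 3.0,
                               coord_idx.size)
        for j, i in enumerate(coord_idx):
            s = gene_shapes[i]
            rng_span = s.max() - s.min()
            rna_shape[i] = 1.0 + (rna_fold[j] - 1.0) * (s - s.min()) / rng_span
    flat_idx = np.flatnonzero(~coordinated)
    rna_shape[flat_idx] *= 1.0 + rng.uniform(0.0, 0.25, (flat_idx.size, 3)) \
        * (rng.random((flat_idx.size, 3)) < 0.5)
    rna_phase = fpkm_async[:, None] * rna_shape / (rna_shape @ async_comp)[:, None]

    genes = pd.DataFrame(
        {
            "regulated": regulated,
            "peak_class": peak_class,
            "coordinated": coordinated,
            "discordant": discordant,
            "is_histone": is_histone,
            "copy_number": copy_number,
            "x_G1": gene_x[:, 0], "x_S": gene_x[:, 1], "x_G2M": gene_x[:, 2],
            "fraction_fold": gene_fold,
            "rna_G1": rna_phase[:, 0], "rna_S": rna_phase[:, 1],
            "rna_G2M": rna_phase[:, 2], "rna_ASYNC": fpkm_async,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    # --- sequences --------------------------------------------------------
    lengths = np.clip(
        np.round(np.exp(rng.normal(math.log(config.seq_length_median),
                                   config.seq_length_sigma, len(iso_ids)))),
        *config.seq_length_bounds,
    ).astype(int)
    base_seqs = _random_sequences(rng, lengths)
    sequences: list[str] = []
    prev_gene = -1
    base = ""
    for idx, (iso_id, gi) in enumerate(zip(iso_ids, iso_gene_idx)):
        if gi != prev_gene:
            base = base_seqs[idx]
            seq = base
            prev_gene = gi
        else:
            # variant isoform: overwrite an interior window so both isoforms
            # gain peptides unique within the gene
            s = list(base)
            wlen = min(60, len(s) // 3)
            start = int(rng.integers(1, len(s) - wlen))
            s[start:start + wlen] = rng.choice(AA_LETTERS, size=wlen, p=AA_PROBS)
            seq = "".join(s)
        if coordinated[gi]:
            seq = _inject_motifs(seq, rng)
        sequences.append(seq)

    iso_regulated = np.zeros(len(iso_ids), dtype=bool)
    iso_fold_arr = np.ones(len(iso_ids))
    iso_expected6 = iso_expected_fr
    iso_fold_arr = iso_expected6.max(axis=1) / iso_expected6.min(axis=1)
    iso_regulated = iso_fold_arr >= lo
    isoforms = pd.DataFrame(
        {
            "gene_id": [gene_ids[gi] for gi in iso_gene_idx],
            "sequence": sequences,
            "a_G1": iso_a[:, 0], "a_S": iso_a[:, 1], "a_G2M": iso_a[:, 2],
            "iso_fold": iso_fold_arr,
            "iso_regulated": iso_regulated,
        },
        index=pd.Index(iso_ids, name="isoform_id"),
    )

    annotations = _generate_annotations(rng, genes)
    return GroundTruth(config, genes, isoforms, expected, annotations,
                       config.fractions)


def _generate_annotations(rng: np.random.Generator, genes: pd.DataFrame) -> pd.DataFrame:
    """GO-like terms plus TFBS labels with built-in enrichment structure."""
    rows: list[tuple[str, str, str]] = []
    n = len(genes)
    go_terms = [f"GO:{i:04d}" for i in range(1, 41)]
    counts = rng.poisson(3.0, n)
    for gid, k in zip(genes.index, counts):
        for t in rng.choice(go_terms, size=min(int(k), len(go_terms)), replace=False):
            rows.append((gid, "GO", str(t)))
    reg = genes["regulated"].to_numpy()
    ccreg = np.where(reg, 0.5, 0.05) > rng.random(n)
    coord = genes["coordinated"].to_numpy()
    nfy = np.where(coord, 0.84, 0.20) > rng.random(n)
    g2mg1 = (genes["peak_class"] == "G2M+G1").to_numpy()
    stat3 = np.where(g2mg1, 0.77, 0.20) > rng.random(n)
    for gid, a, b, c in zip(genes.index, ccreg, nfy, stat3):
        if a:
            rows.append((gid, "GO", "GO:CCREG"))
        if b:
            rows.append((gid, "TFBS", "NFY"))
        if c:
            rows.append((gid, "TFBS", "STAT3"))
    return pd.DataFrame(rows, columns=["gene_id", "term_type", "term_id"])


# ---------------------------------------------------------------------------
# evidence table


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size))


def generate_evidence_table(truth: GroundTruth,
                            config: SimulationConfig | None = None) -> pd.DataFrame:
    """Long-format peptide evidence: one row per detected peptide per sample.

    Intensity = parent expected per-cell intensity x fixed per-peptide
    response factor x multiplicative log-normal noise; MS/MS counts are
    Poisson with a rate increasing in log intensity; detection probability
    is logistic in log intensity (abundance-dependent missingness).
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 1)
    mn, mx = config.peptide_length_bounds
    specs = (
        DigestSpec(TRYPSIN_DD, config.evidence_missed_cleavages, mn, mx),
        DigestSpec(LYSC, config.evidence_missed_cleavages, mn, mx),
    )

    iso_a = truth.isoforms[["a_G1", "a_S", "a_G2M"]].to_numpy()
    iso_index = {iso: k for k, iso in enumerate(truth.isoforms.index)}
    iso_seq = truth.isoforms["sequence"]
    gene_of = truth.isoforms["gene_id"]

    # enumerate (gene, peptide, protease) rows with within-gene isoform sets
    recs: list[tuple[str, str, str, tuple[str, ...]]] = []
    for gid, group in iso_seq.groupby(gene_of, sort=True):
        per_prot: dict[tuple[str, str], set[str]] = {}
        for iso_id, seq in group.items():
            for spec in specs:
                for pep in digest_sequence(seq, spec):
                    per_prot.setdefault((pep.sequence, spec.protease), set()).add(iso_id)
        for (pseq, prot), isos in sorted(per_prot.items()):
            recs.append((gid, pseq, prot, tuple(sorted(isos))))

    n_rows = len(recs)
    pep_seqs = [r[1] for r in recs]
    unique_seqs = sorted(set(pep_seqs))
    # fixed per-peptide response factor (log-normal on the natural scale)
    resp_vals = np.exp(rng.normal(0.0, config.response_sigma, len(unique_seqs)))
    resp_map = dict(zip(unique_seqs, resp_vals))
    response = np.array([resp_map[s] for s in pep_seqs])

    parent = np.zeros((n_rows, 3))
    for i, (_, _, _, isos) in enumerate(recs):
        for iso in isos:
            parent[i] += iso_a[iso_index[iso]]

    M = composition_matrix(truth.fractions)
    async_comp = cell_count_weights(truth.fractions) @ M
    comp7 = np.vstack([M, async_comp])            # 7 x 3
    expected = parent @ comp7.T                   # n_rows x 7

    def _measure(exp_mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        noise = _lognormal_factor(rng, config.noise_cv, exp_mat.shape)
        inten = exp_mat * noise
        logi = np.log10(np.clip(inten, 1e-12, None))
        if np.isneginf(config.detect_midpoint):
            detected = np.ones(exp_mat.shape, dtype=bool)
        else:
            p = 1.0 / (1.0 + np.exp(-config.detect_slope * (logi - config.detect_midpoint)))
            detected = rng.random(exp_mat.shape) < p
        # spectral-count rate: linear in intensity with duty-cycle saturation
        lam = np.clip(config.msms_ref_rate * inten / config.msms_ref_intensity,
                      0.02, config.msms_max_rate)
        msms = rng.poisson(lam)
        return inten, detected, msms

    intensity, detected, msms = _measure(expected * response[:, None])

    frames = []
    base = pd.DataFrame(
        {
            "sequence": pep_seqs,
            "protease": [r[2] for r in recs],
            "gene_id": [r[0] for r in recs],
            "proteins": [";".join(r[3]) for r in recs],
            "modifications": "Unmodified",
            "phospho_sites": "",
            "is_contaminant": False,
            "is_reverse": False,
        }
    )
    frames.append(_to_long(base, intensity, detected, msms))

    # --- chemically modified duplicates (sample-prep artifacts) -----------
    seq_arr = np.array(pep_seqs, dtype=object)
    has_m = np.char.find(seq_arr.astype(str), "M") >= 0
    has_nq = (np.char.find(seq_arr.astype(str), "N") >= 0) | \
             (np.char.find(seq_arr.astype(str), "Q") >= 0)
    for mod, mask_aa, rate in (
        ("Oxidation (M)", has_m, config.oxidation_rate),
        ("Deamidation (NQ)", has_nq, config.deamidation_rate),
    ):
        pick = np.flatnonzero(mask_aa & (rng.random(n_rows) < rate))
        if pick.size == 0:
            continue
        stoich = rng.uniform(0.05, 0.3, pick.size)
        sub = base.iloc[pick].copy()
        sub["modifications"] = mod
        exp_mod = expected[pick] * (response[pick] * stoich)[:, None]
        inten_m, det_m, msms_m = _measure(exp_mod)
        frames.append(_to_long(sub, inten_m, det_m, msms_m))

    # --- phosphopeptides ---------------------------------------------------
    frames.append(_phospho_rows(rng, config, recs, parent, response, comp7,
                                _measure, dict(iso_seq)))

    # --- contaminants and reverse decoys -----------------------------------
    frames.append(_background_rows(rng, config, "CON", config.contaminant_rate))
    frames.append(_background_rows(rng, config, "REV", config.decoy_rate))

    evidence = pd.concat([f for f in frames if f is not None and len(f)],
                         ignore_index=True)
    evidence.insert(0, "peptide_id", np.arange(len(evidence)))
    return evidence


def _to_long(base: pd.DataFrame, intensity: np.ndarray, detected: np.ndarray,
             msms: np.ndarray) -> pd.DataFrame:
    """Explode a row-per-peptide block into detected (peptide, sample) rows."""
    n = len(base)
    k = len(SAMPLES)
    rep = base.loc[base.index.repeat(k)].reset_index(drop=True)
    rep["sample"] = np.tile(np.array(SAMPLES, dtype=object), n)
    rep["intensity"] = intensity.reshape(-1)
    rep["msms_count"] = msms.reshape(-1)
    return rep.loc[detected.reshape(-1)].reset_index(drop=True)


def _phospho_rows(rng, config, recs, parent, response, comp7, measure, fasta):
    """Phosphopeptide evidence: a configurable share of S/T/Y-containing
    peptides carries a phospho form; a subset has independently regulated
    site stoichiometry (phase-shaped multiplier)."""
    n_rows = len(recs)
    # enumerate the protein-level S/T/Y site universe (overlapping peptides
    # covering a residue map to one site), then sample sites per residue
    # class without replacement: the site-level S/T/Y distribution matches
    # sty_mix by construction
    offsets = [fasta[r[3][0]].find(r[1]) for r in recs]
    site_map: dict[tuple[str, int, str], list[tuple[int, int]]] = {}
    for i, (_, pseq, _, isos) in enumerate(recs):
        off = offsets[i]
        for k, aa in enumerate(pseq):
            if aa in "STY":
                site_map.setdefault((isos[0], off + k, aa), []).append((i, k))
    by_res = {aa: sorted(key for key in site_map if key[2] == aa)
              for aa in "STY"}
    if not any(by_res.values()):
        return None
    n_events = int(round(config.phospho_rate * n_rows))
    if n_events == 0:
        return None
    want = rng.multinomial(n_events, config.sty_mix)
    M = comp7[:6]
    pick_list: list[int] = []
    site_rows: list[list[tuple[str, int]]] = []
    shape_list: list[np.ndarray] = []
    for aa, n_want in zip("STY", want):
        keys = by_res[aa]
        n_take = min(int(n_want), len(keys))
        if n_take == 0:
            continue
        chosen = rng.choice(len(keys), size=n_take, replace=False)
        for ci in np.sort(chosen):
            iso, pos, res = keys[ci]
            carriers = site_map[(iso, pos, res)]
            i, pos_in_pep = carriers[int(rng.integers(0, len(carriers)))]
            sites = [(res, pos_in_pep)]
            pseq = recs[i][1]
            if rng.random() < config.multisite_rate:
                others = [(a, k) for k, a in enumerate(pseq)
                          if a in "STY" and k != pos_in_pep]
                if others:
                    sites.append(others[int(rng.integers(0, len(others)))])
            shape = np.ones(3)
            if rng.random() < config.phospho_regulated_rate:
                cls = str(rng.choice(["G1", "S", "G2M"]))
                cap = 0.97 * max_fraction_fold(cls, M)
                shape = solve_phase_shape(cls, min(rng.uniform(2.3, 5.0), cap), M)
            pick_list.append(i)
            site_rows.append(sites)
            shape_list.append(shape)
    if not pick_list:
        return None
    pick = np.array(pick_list)
    shapes = np.array(shape_list)
    stoich = rng.uniform(0.02, 0.2, pick.size)
    exp_ph = (parent[pick] * shapes) @ comp7.T * (response[pick] * stoich)[:, None]
    inten, det, msms = measure(exp_ph)

    sub_rows = []
    for j, i in enumerate(pick):
        gid, pseq, prot, isos = recs[i]
        # site positions are 1-based within the leading matching isoform so
        # overlapping peptides covering the same residue share a site key
        site_strs = []
        for res, pos_in_pep in site_rows[j]:
            site_strs.append(f"{res}{offsets[i] + pos_in_pep + 1}")
        sub_rows.append((pseq, prot, gid, ";".join(isos),
                         "Phospho (STY)", ";".join(sorted(site_strs))))
    sub = pd.DataFrame(sub_rows, columns=[
        "sequence", "protease", "gene_id", "proteins", "modifications",
        "phospho_sites"])
    sub["is_contaminant"] = False
    sub["is_reverse"] = False
    return _to_long(sub, inten, det, msms)


def _background_rows(rng, config, kind: str, rate: float):
    """Contaminant / reverse-decoy peptide rows (flat intensity profiles)."""
    n_prot = int(round(rate * config.n_genes))
    if n_prot == 0:
        return None
    lengths = np.full(n_prot, 200)
    seqs = _random_sequences(rng, lengths)
    mn, mx = config.peptide_length_bounds
    spec = DigestSpec(TRYPSIN_DD, 0, mn, mx)
    rows = []
    for i, seq in enumerate(seqs):
        pid = f"{kind}_{i + 1:03d}"
        for pep in digest_sequence(seq, spec)[:6]:
            rows.append((pep.sequence, TRYPSIN_DD, pid, pid, "Unmodified", ""))
    if not rows:
        return None
    sub = pd.DataFrame(rows, columns=[
        "sequence", "protease", "gene_id", "proteins", "modifications",
        "phospho_sites"])
    sub["is_contaminant"] = kind == "CON"
    sub["is_reverse"] = kind == "REV"
    level = 10.0 ** rng.uniform(3, 6, len(sub))
    exp = np.tile(level[:, None], (1, len(SAMPLES)))
    noise = _lognormal_factor(rng, max(config.noise_cv, 0.05), exp.shape)
    inten = exp * noise
    msms = rng.poisson(3.0, exp.shape)
    det = np.ones(exp.shape, dtype=bool)
    return _to_long(sub, inten, det, msms)


# ---------------------------------------------------------------------------
# RNA table


def generate_rna_table(truth: GroundTruth,
                       config: SimulationConfig | None = None) -> pd.DataFrame:
    """FPKM per gene x pooled sample x 2 biological x 2 technical replicates
    with multiplicative log-normal noise. Histone-flagged genes are included
    so the downstream removal rule is exercisable."""
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 2)
    genes = truth.genes
    truth_vals = genes[["rna_G1", "rna_S", "rna_G2M", "rna_ASYNC"]].to_numpy()
    samples = ("G1", "S", "G2M", "ASYNC")
    n = len(genes)
    rows = []
    bio_cv = config.rna_noise_cv
    tech_cv = config.rna_noise_cv / 2.0
    for si, sample in enumerate(samples):
        for b in (1, 2):
            bio = _lognormal_factor(rng, bio_cv, n)
            for t in (1, 2):
                tech = _lognormal_factor(rng, tech_cv, n)
                rows.append(pd.DataFrame({
                    "gene_id": genes.index,
                    "sample": sample,
                    "bio_rep": b,
                    "tech_rep": t,
                    "fpkm": truth_vals[:, si] * bio * tech,
                    "is_histone": genes["is_histone"].to_numpy(),
                }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# output bundle


def write_outputs(truth: GroundTruth, evidence: pd.DataFrame,
                  rna: pd.DataFrame, out_dir: str | Path) -> dict[str, Path]:
    """Write every file the downstream modules consume, plus the ground
    truth (for tests). TSV everywhere; FASTA for the isoform sequences."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["evidence"] = out / "evidence.tsv"
    evidence.to_csv(paths["evidence"], sep="\t", index=False, float_format="%.8g")

    paths["fpkm"] = out / "fpkm.tsv"
    rna.to_csv(paths["fpkm"], sep="\t", index=False, float_format="%.8g")

    paths["fasta"] = out / "isoforms.fasta"
    with open(paths["fasta"], "w") as fh:
        for iso_id, seq in truth.fasta.items():
            fh.write(f">{iso_id}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")

    paths["fractions"] = out / "fractions.tsv"
    fractions_to_frame(truth.fractions).to_csv(paths["fractions"], sep="\t",
                                               index=False, float_format="%.8g")

    paths["annotations"] = out / "annotations.tsv"
    truth.annotations.to_csv(paths["annotations"], sep="\t", index=False)

    paths["genes_truth"] = out / "ground_truth_genes.tsv"
    truth.genes.to_csv(paths["genes_truth"], sep="\t", float_format="%.8g")
    paths["isoforms_truth"] = out / "ground_truth_isoforms.tsv"
    truth.isoforms.to_csv(paths["isoforms_truth"], sep="\t", float_format="%.8g")
    return paths


def simulate(config: SimulationConfig, out_dir: str | Path | None = None):
    """Convenience wrapper: ground truth + evidence + RNA (+ files)."""
    truth = generate_ground_truth(config)
    evidence = generate_evidence_table(truth, config)
    rna = generate_rna_table(truth, config)
    if out_dir is not None:
        write_outputs(truth, evidence, rna, out_dir)
    return truth, evidence, rna
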