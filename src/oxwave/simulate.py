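"""Synthetic ischemia/reperfusion TMT open-search experiments with known truth.

The generator emulates the statistical structure the downstream analysis
assumes: a baseline + multi-time-point design (n biological replicates per
group, one TMT plex per replicate with a pooled-baseline reference channel),
an early wave of irreversible mono-oxidation on Lys/Phe/Asn/Asp peaking at
the first reperfusion time, a later wave of mono-/di-/tri-oxidation on
Cys/Trp, a reversible Cys-oxidation wave read out through the differential
alkylation tag (carbamidomethyl = reduced, methylthio = reversibly
oxidized), decoy and false-target PSMs, a systematic mass-calibration
offset, artifact ΔM populations, and category-organized protein abundance
effects (an immune category rising late, a mitochondrial category falling
at the last time point).

Reporter noise is lognormal (Gaussian in log2 space) and mass error is
Gaussian in ppm. Wave templates are expressed in Zp units; the generator
converts them to log2 deviations through the peptide-level standard
deviation implied by its own noise model, so a template value of 2.5 is
expected to come back as a Zp of about 2.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import masses as M
from .io import ANY_RESIDUE, DesignTable, FastaDatabase, ModAnnotation

DEFAULT_TIMEPOINTS_8 = ["baseline", "20min", "40min", "80min", "2h", "6h", "12h", "24h"]

WAVE1_RESIDUES = "KFND"
WAVE2_RESIDUES = "CW"

MOD_OXIDATION = "Oxidation"
MOD_DIOXIDATION = "Dioxidation"
MOD_TRIOXIDATION = "Trioxidation"
MOD_METHYLTHIO_EXCHANGE = "Methylthio_exchange"


def default_mod_list() -> list[ModAnnotation]:
    """The curated known-mass-shift list the simulator's PTMs are drawn from.

    Artifact and combination entries carry flags so the curation filter has
    something to discard; deamidation is included as a realistic near-miss
    for the +1 isotope-error artifact (19 mDa apart, outside the default
    10 mDa match tolerance).
    """
    f = frozenset
    return [
        ModAnnotation("Unmodified", 0.0, f({ANY_RESIDUE})),
        ModAnnotation(MOD_OXIDATION, M.OXIDATION, f("MWCKFNDPYR")),
        ModAnnotation(MOD_DIOXIDATION, M.DIOXIDATION, f("CWMFY")),
        ModAnnotation(MOD_TRIOXIDATION, M.TRIOXIDATION, f("CWY")),
        ModAnnotation(MOD_METHYLTHIO_EXCHANGE, M.METHYLTHIO_EXCHANGE, f("C")),
        ModAnnotation("Deamidation", M.DEAMIDATION, f("NQ")),
        ModAnnotation("Isotope_error_1", M.ISOTOPE_SPACING, f({ANY_RESIDUE}), is_artifact=True),
        ModAnnotation("Isotope_error_2", 2 * M.ISOTOPE_SPACING, f({ANY_RESIDUE}), is_artifact=True),
        ModAnnotation("Oxidation+Carbamidomethyl", M.OXIDATION + M.CARBAMIDOMETHYL,
                      f("C"), is_combination=True),
    ]


def _default_wave1(n: int) -> tuple[float, ...]:
    # peaks at the first post-baseline time point, decays quickly
    return tuple(0.0 if i == 0 else 2.5 * 0.45 ** (i - 1) for i in range(n))


def _default_wave2(n: int, peak: float = 2.5) -> tuple[float, ...]:
    # smooth bump peaking in the middle/late course, absent at baseline
    c = max(2, round(0.7 * (n - 1)))
    return tuple(0.0 if i == 0 else peak * math.exp(-0.5 * ((i - c) / 1.8) ** 2)
                 for i in range(n))


@dataclass
class SimConfig:
    """Study-design and noise parameters of one simulated experiment."""

    n_proteins: int = 150
    peptides_per_protein: int = 8
    n_timepoints: int = 8
    n_replicates: int = 4
    channels_per_plex: int = 10
    frac_modified: float = 0.2
    wave1_template: tuple[float, ...] | None = None
    wave2_template: tuple[float, ...] | None = None
    redox_wave_template: tuple[float, ...] | None = None
    decoy_fraction: float = 0.12
    false_target_fraction: float | None = None   # None = same as decoy_fraction
    calib_offset_ppm: float = 0.0
    artifact_deltams: tuple[float, ...] = (
        M.ISOTOPE_SPACING,
        2 * M.ISOTOPE_SPACING,
        M.OXIDATION + M.CARBAMIDOMETHYL,
    )
    category_effects: dict[str, tuple[float, ...]] | None = None
    seed: int = 0

    # noise model and plumbing
    reporter_sigma: float = 0.18       # per-channel log2 reporter noise
    sigma_peptide: float = 0.10        # extra peptide-level log2 SD
    sigma_protein: float = 0.10        # extra protein-level (biological) log2 SD
    mass_noise_ppm: float = 1.5        # precursor mass error SD
    psms_per_peptide: int = 2          # spectra per peptidoform per plex
    peptide_detect_prob: float = 0.95  # chance a peptidoform is sampled in a plex
    frac_redox: float = 0.2            # fraction of unmodified Cys peptides with redox dynamics
    redox_base_fraction: float = 0.2   # baseline reversibly-oxidized fraction
    mod_split: tuple[float, float, float] = (0.45, 0.35, 0.20)  # wave1/wave2/artifact
    target_score_mean: float = 0.45    # corrected-XCorr-like score scale
    decoy_score_shift: float = 0.30
    score_sigma: float = 0.12
    tag_mass_noise: float = 0.002      # SD of the localized Cys tag mass, Da
    site_error_rate: float = 0.02      # per-PSM chance of a mislocalized site
    category_size: int = 25
    deltam_range: tuple[float, float] = (-60.0, 60.0)
    log2_base_mean: float = 17.0
    log2_base_sd: float = 1.2
    mod_stoichiometry: float = 0.1
    timepoint_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.channels_per_plex < self.n_timepoints + 1:
            raise ValueError("need one reference channel plus one channel per group")
        if self.false_target_fraction is None:
            self.false_target_fraction = self.decoy_fraction
        for name in ("frac_modified", "decoy_fraction", "false_target_fraction",
                     "peptide_detect_prob", "frac_redox", "redox_base_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.decoy_fraction + self.false_target_fraction >= 0.8:
            raise ValueError("decoy_fraction + false_target_fraction must be < 0.8 "
                             "to leave room for correct targets")
        if self.wave1_template is None:
            self.wave1_template = _default_wave1(self.n_timepoints)
        if self.wave2_template is None:
            self.wave2_template = _default_wave2(self.n_timepoints)
        if self.redox_wave_template is None:
            self.redox_wave_template = _default_wave2(self.n_timepoints, peak=2.4)
        for name in ("wave1_template", "wave2_template", "redox_wave_template"):
            t = getattr(self, name)
            if len(t) != self.n_timepoints:
                raise ValueError(f"{name} must have length n_timepoints={self.n_timepoints}")
        if self.category_effects is None:
            late = tuple(0.5 if i >= math.ceil(self.n_timepoints / 2) else 0.0
                         for i in range(self.n_timepoints))
            mito = tuple(-0.5 if i == self.n_timepoints - 1 else 0.0
                         for i in range(self.n_timepoints))
            self.category_effects = {"immune": late, "mitochondrial": mito}
        for name, t in self.category_effects.items():
            if len(t) != self.n_timepoints:
                raise ValueError(f"category_effects[{name!r}] must have length n_timepoints")
        if self.timepoint_labels is None:
            self.timepoint_labels = (
                tuple(DEFAULT_TIMEPOINTS_8) if self.n_timepoints == 8
                else tuple(["baseline"] + [f"t{i}" for i in range(1, self.n_timepoints)])
            )
        if len(self.timepoint_labels) != self.n_timepoints:
            raise ValueError("timepoint_labels must have length n_timepoints")

    @property
    def sigma_zp(self) -> float:
        """Peptide-level log2 SD implied by the noise model: converts wave
        templates (Zp units) into injected log2 deviations. The factor 2 on
        the reporter variance reflects that each log2 ratio contains both
        the sample-channel and the reference-channel noise."""
        return math.sqrt(self.sigma_peptide ** 2
                         + 2 * self.reporter_sigma ** 2 / self.psms_per_peptide)

    def null(self) -> "SimConfig":
        """A copy with every injected effect switched off."""
        zeros = tuple(0.0 for _ in range(self.n_timepoints))
        return replace(self, wave1_template=zeros, wave2_template=zeros,
                       redox_wave_template=zeros,
                       category_effects={k: zeros for k in self.category_effects})


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    proteins: pd.DataFrame                 # accession, category
    peptides: pd.DataFrame                 # peptide, protein
    protein_log2fc: pd.DataFrame           # protein x timepoint
    modified_peptide_truth: pd.DataFrame   # pepform_id, peptide, protein, wave_id, ...
    redox_truth: pd.DataFrame              # peptide-indexed oxidized fraction per timepoint
    injected_deltam_peaks: list[float]
    decoy_ids: set[str]
    categories: dict[str, set[str]] = field(default_factory=dict)
    timepoints: list[str] = field(default_factory=list)


def make_design(config: SimConfig) -> DesignTable:
    """One 10-plex per biological replicate: channel 1 is the pooled-baseline
    reference, channels 2..(n_groups+1) hold replicate r of every group."""
    rows = []
    for r in range(config.n_replicates):
        plex = f"plex{r + 1}"
        rows.append((plex, 1, f"{plex}_ref", "reference", "", True))
        for g, tp in enumerate(config.timepoint_labels):
            rows.append((plex, 2 + g, f"{tp}_r{r + 1}", tp, tp, False))
    frame = pd.DataFrame(rows, columns=[
        "plex_id", "channel_index", "sample_id", "group_label",
        "timepoint_label", "is_reference"])
    return DesignTable(frame)


def _random_peptide(rng: np.random.Generator) -> str:
    length = int(rng.integers(8, 17))
    body = "".join(rng.choice(list(M.AMINO_ACIDS), size=length - 1))
    return body + ("K" if rng.random() < 0.5 else "R")


def _ensure_residue(peptide: str, residues: str, rng: np.random.Generator) -> str:
    if any(r in residues for r in peptide[:-1]):
        return peptide
    pos = int(rng.integers(0, len(peptide) - 1))
    return peptide[:pos] + str(rng.choice(list(residues))) + peptide[pos + 1:]


def _site_of(peptide: str, residues: str, rng: np.random.Generator) -> int:
    positions = [i + 1 for i, aa in enumerate(peptide) if aa in residues]
    return int(rng.choice(positions))


def pepform_id(peptide: str, ptm_name: str, site: int) -> str:
    return f"{peptide}|{ptm_name}|{site}"


def generate_ground_truth(config: SimConfig) -> GroundTruth:
    rng = np.random.default_rng(config.seed)
    tps = list(config.timepoint_labels)
    G = config.n_timepoints

    # proteins and categories
    accessions = [f"P{i + 1:04d}" for i in range(config.n_proteins)]
    categories: dict[str, set[str]] = {}
    cat_of: dict[str, str] = {}
    pool = list(accessions)
    for name in config.category_effects:
        members, pool = pool[:config.category_size], pool[config.category_size:]
        categories[name] = set(members)
        cat_of.update({a: name for a in members})
    j = 0
    while pool:
        members, pool = pool[:config.category_size], pool[config.category_size:]
        name = f"cat{j:03d}"
        categories[name] = set(members)
        cat_of.update({a: name for a in members})
        j += 1
    proteins = pd.DataFrame({"accession": accessions,
                             "category": [cat_of[a] for a in accessions]})

    # peptides (unique across the database)
    seen: set[str] = set()
    pep_rows = []
    for acc in accessions:
        for _ in range(config.peptides_per_protein):
            p = _random_peptide(rng)
            while p in seen:
                p = _random_peptide(rng)
            seen.add(p)
            pep_rows.append((p, acc))
    peptides = pd.DataFrame(pep_rows, columns=["peptide", "protein"])

    # protein log2 fold changes from category effects
    fc = np.zeros((config.n_proteins, G))
    for name, template in config.category_effects.items():
        idx = [i for i, a in enumerate(accessions) if a in categories[name]]
        fc[idx, :] = np.asarray(template, dtype=float)
    protein_log2fc = pd.DataFrame(fc, index=accessions, columns=tps)

    # PTM assignment
    mods = {m.name: m for m in default_mod_list()}
    artifact_names = []
    for dm in config.artifact_deltams:
        match = min((m for m in mods.values() if m.is_artifact or m.is_combination),
                    key=lambda m: abs(m.delta_mass - dm), default=None)
        if match is not None and abs(match.delta_mass - dm) < 1e-3:
            artifact_names.append(match.name)
        else:
            name = f"artifact_{dm:+.5f}"
            mods[name] = ModAnnotation(name, dm, frozenset({ANY_RESIDUE}), is_artifact=True)
            artifact_names.append(name)

    order = rng.permutation(len(peptides))
    n_mod = round(config.frac_modified * len(peptides))
    chosen = order[:n_mod]
    f1, f2, _ = config.mod_split
    n1 = round(f1 * n_mod)
    n2 = round(f2 * n_mod)
    truth_rows = []
    pep_seqs = peptides["peptide"].to_list()
    for k, pi in enumerate(chosen):
        pep = pep_seqs[pi]
        acc = peptides["protein"].iloc[pi]
        if k < n1:
            pep = _ensure_residue(pep, WAVE1_RESIDUES, rng)
            site = _site_of(pep, WAVE1_RESIDUES, rng)
            name = MOD_OXIDATION
            wave = "wave1"
        elif k < n1 + n2:
            pep = _ensure_residue(pep, WAVE2_RESIDUES, rng)
            site = _site_of(pep, WAVE2_RESIDUES, rng)
            name = str(rng.choice([MOD_OXIDATION, MOD_DIOXIDATION, MOD_TRIOXIDATION]))
            wave = "wave2"
        else:
            site = int(rng.integers(1, len(pep) + 1))
            name = str(rng.choice(artifact_names))
            wave = "artifact"
        pep_seqs[pi] = pep  # keep any forced residue substitution
        truth_rows.append((pepform_id(pep, name, site), pep, acc, wave, name,
                           mods[name].delta_mass, site, pep[site - 1]))
    peptides["peptide"] = pep_seqs

    # reversible Cys oxidation on a subset of the remaining Cys peptides
    sigma_zp = config.sigma_zp
    template = np.asarray(config.redox_wave_template, dtype=float)
    modified_idx = set(chosen.tolist())
    cys_idx = [i for i in range(len(peptides))
               if i not in modified_idx and "C" in pep_seqs[i][:-1] + pep_seqs[i][-1]]
    n_redox = round(config.frac_redox * len(cys_idx))
    redox_rows = []
    for pi in rng.permutation(cys_idx)[:n_redox]:
        pep = pep_seqs[pi]
        acc = peptides["protein"].iloc[pi]
        site = _site_of(pep, "C", rng)
        fractions = np.clip(config.redox_base_fraction * 2.0 ** (template * sigma_zp),
                            0.02, 0.9)
        redox_rows.append([pep, acc, site, *fractions])
        truth_rows.append((pepform_id(pep, MOD_METHYLTHIO_EXCHANGE, site), pep, acc,
                           "redox", MOD_METHYLTHIO_EXCHANGE, M.METHYLTHIO_EXCHANGE,
                           site, "C"))

    modified_peptide_truth = pd.DataFrame(
        truth_rows, columns=["pepform_id", "peptide", "protein", "wave_id",
                             "ptm_name", "ptm_delta", "site_position", "site_residue"])
    redox_truth = pd.DataFrame(redox_rows,
                               columns=["peptide", "protein", "site_position", *tps])

    injected = sorted({0.0} | set(modified_peptide_truth["ptm_delta"]
                                  .astype(float).round(6)))
    decoy_ids = {f"DECOY_{a}" for a in accessions}
    return GroundTruth(proteins, peptides, protein_log2fc, modified_peptide_truth,
                       redox_truth, injected, decoy_ids, categories, tps)


def make_fasta(truth: GroundTruth, decoy_prefix: str = "DECOY_") -> FastaDatabase:
    """Concatenated target-decoy database; a protein's sequence is the
    concatenation of its tryptic peptides, decoys are reversed targets."""
    seqs: dict[str, str] = {}
    grouped = truth.peptides.groupby("protein", sort=True)["peptide"].apply("".join)
    for acc, seq in grouped.items():
        seqs[acc] = seq
    for acc, seq in grouped.items():
        seqs[f"{decoy_prefix}{acc}"] = seq[::-1]
    return FastaDatabase(seqs, decoy_prefix)


def _build_pepforms(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """One row per peptidoform with its per-time log2 deviation vector."""
    tps = truth.timepoints
    G = len(tps)
    sigma_zp = config.sigma_zp

    forms = []
    dev_rows = []
    redox_by_pep = truth.redox_truth.set_index("peptide") if len(truth.redox_truth) else None

    for pep, acc in truth.peptides.itertuples(index=False):
        dev = np.zeros(G)
        tag = "CAM" if "C" in pep else ""
        if redox_by_pep is not None and pep in redox_by_pep.index:
            f = redox_by_pep.loc[pep, tps].to_numpy(dtype=float)
            dev = np.log2((1.0 - f) / (1.0 - f[0]))
        forms.append((pepform_id(pep, "", 0), pep, acc, "none", "", 0.0, 0, tag, 1.0))
        dev_rows.append(dev)

    w1 = np.asarray(config.wave1_template, dtype=float) * sigma_zp
    w2 = np.asarray(config.wave2_template, dtype=float) * sigma_zp
    for row in truth.modified_peptide_truth.itertuples(index=False):
        if row.wave_id == "wave1":
            dev, tag, stoich = w1, ("CAM" if "C" in row.peptide else ""), config.mod_stoichiometry
        elif row.wave_id == "wave2":
            dev, tag, stoich = w2, ("CAM" if "C" in row.peptide else ""), config.mod_stoichiometry
        elif row.wave_id == "artifact":
            dev, tag, stoich = np.zeros(G), ("CAM" if "C" in row.peptide else ""), config.mod_stoichiometry
        else:  # redox: abundance of the methylthio form tracks the oxidized fraction
            f = redox_by_pep.loc[row.peptide, tps].to_numpy(dtype=float)
            dev, tag, stoich = np.log2(f / f[0]), "MMTS", float(f[0])
        forms.append((row.pepform_id, row.peptide, row.protein, row.wave_id,
                      row.ptm_name, row.ptm_delta, row.site_position, tag, stoich))
        dev_rows.append(np.asarray(dev, dtype=float))

    out = pd.DataFrame(forms, columns=["pepform_id", "peptide", "protein", "wave_id",
                                       "ptm_name", "ptm_delta", "site_position",
                                       "cys_tag", "stoichiometry"])
    out["dev"] = [np.asarray(d) for d in dev_rows]
    return out


def simulate_psm_table(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Simulate the open-search PSM table for one experiment.

    Returns a DataFrame with the documented PSM columns, reporter
    intensities for every channel, the localized Cys tag mass where the
    peptide contains Cys, and ``truth_*`` columns (label, peptidoform,
    wave, ΔM, ppm offset) that the pipeline strips before writing the
    search-style table.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    design = make_design(config)
    G = config.n_timepoints
    R = config.n_replicates
    C = config.channels_per_plex
    tps = truth.timepoints

    forms = _build_pepforms(truth, config)
    n_forms = len(forms)
    prot_index = {a: i for i, a in enumerate(truth.protein_log2fc.index)}
    form_prot = forms["protein"].map(prot_index).to_numpy()
    fc = truth.protein_log2fc.to_numpy()                      # n_prot x G
    dev = np.stack(forms["dev"].to_numpy())                   # n_forms x G

    # detection: which forms appear in which plex
    detected = rng.random((n_forms, R)) < config.peptide_detect_prob
    form_u, plex_u = np.nonzero(detected)
    form_u = np.repeat(form_u, config.psms_per_peptide)
    plex_u = np.repeat(plex_u, config.psms_per_peptide)
    n_u = len(form_u)

    # per-level log2 noise
    n_samples = G * R                                         # sample index = r*G + g
    eps_q = rng.normal(0.0, config.sigma_protein, (len(prot_index), n_samples))
    eps_p = rng.normal(0.0, config.sigma_peptide, (n_forms, n_samples))
    eps_s = rng.normal(0.0, config.reporter_sigma, (n_u, C))

    log2_base = (config.log2_base_mean
                 + rng.normal(0.0, config.log2_base_sd, n_forms)
                 + np.log2(forms["stoichiometry"].to_numpy(dtype=float)))
    base_u = log2_base[form_u]
    prot_u = form_prot[form_u]

    log2I = np.empty((n_u, C))
    log2I[:, 0] = base_u + eps_s[:, 0]                        # reference channel
    for c in range(1, C):
        g = c - 1
        if g < G:
            samp = plex_u * G + g
            log2I[:, c] = (base_u + fc[prot_u, g] + dev[form_u, g]
                           + eps_q[prot_u, samp] + eps_p[form_u, samp] + eps_s[:, c])
        else:                                                 # idle channel
            log2I[:, c] = base_u + eps_s[:, c]
    intensities = 2.0 ** log2I

    peptide_u = forms["peptide"].to_numpy()[form_u]
    theo_by_form = M.peptide_masses(forms["peptide"])
    theo_u = theo_by_form[form_u]
    true_dm_u = forms["ptm_delta"].to_numpy(dtype=float)[form_u]
    score_u = np.clip(rng.normal(config.target_score_mean, config.score_sigma, n_u),
                      0.01, None)

    # localized site, with occasional localization errors
    site_u = forms["site_position"].to_numpy()[form_u].astype(float)
    has_site = site_u > 0
    err = (rng.random(n_u) < config.site_error_rate) & has_site
    if err.any():
        lengths = np.array([len(p) for p in peptide_u[err]])
        shift = rng.integers(1, np.maximum(lengths, 2))
        site_u[err] = (site_u[err] - 1 + shift) % lengths + 1

    # Cys tag mass: the alkylation tag the search localized on Cys
    tag_u = forms["cys_tag"].to_numpy()[form_u]
    tag_mass = np.full(n_u, np.nan)
    tag_mass[tag_u == "CAM"] = M.CARBAMIDOMETHYL
    tag_mass[tag_u == "MMTS"] = M.METHYLTHIO
    noisy = ~np.isnan(tag_mass)
    tag_mass[noisy] += rng.normal(0.0, config.tag_mass_noise, int(noisy.sum()))

    correct = pd.DataFrame({
        "peptide": peptide_u,
        "charge": rng.integers(2, 4, n_u),
        "theoretical_mass": theo_u,
        "score": score_u,
        "is_decoy": np.zeros(n_u, dtype=bool),
        "protein": forms["protein"].to_numpy()[form_u],
        "site_position": site_u,
        "plex_id": np.array([f"plex{r + 1}" for r in range(R)])[plex_u],
        "cys_tag_mass": tag_mass,
        "truth_label": "correct",
        "truth_pepform": forms["pepform_id"].to_numpy()[form_u],
        "truth_wave": forms["wave_id"].to_numpy()[form_u],
        "truth_delta_mass": true_dm_u,
    })
    frames = [correct]
    reporters = [intensities]

    # decoys and matched false targets: uniform ΔM, shifted-down scores
    fd, ff = config.decoy_fraction, config.false_target_fraction
    denom = max(1.0 - fd - ff, 1e-9)
    target_peps = truth.peptides["peptide"].to_numpy()
    target_prots = truth.peptides["protein"].to_numpy()
    for label, frac in (("decoy", fd), ("false_target", ff)):
        n_extra = round(n_u / denom * frac)
        if n_extra == 0:
            continue
        pick = rng.integers(0, len(target_peps), n_extra)
        if label == "decoy":
            peps = np.array([p[:-1][::-1] + p[-1] for p in target_peps[pick]])
            prots = np.array([f"DECOY_{a}" for a in target_prots[pick]])
        else:
            peps = target_peps[pick]
            prots = target_prots[pick]
        theo = M.peptide_masses(peps)
        lo, hi = config.deltam_range
        dm = rng.uniform(lo, hi, n_extra)
        lengths = np.array([len(p) for p in peps])
        frames.append(pd.DataFrame({
            "peptide": peps,
            "charge": rng.integers(2, 4, n_extra),
            "theoretical_mass": theo,
            "score": np.clip(rng.normal(config.target_score_mean - config.decoy_score_shift,
                                        config.score_sigma, n_extra), 0.01, None),
            "is_decoy": np.full(n_extra, label == "decoy"),
            "protein": prots,
            "site_position": rng.integers(1, lengths + 1).astype(float),
            "plex_id": np.array([f"plex{r + 1}" for r in range(R)])[
                rng.integers(0, R, n_extra)],
            "cys_tag_mass": np.nan,
            "truth_label": label,
            "truth_pepform": "",
            "truth_wave": "",
            "truth_delta_mass": dm,
        }))
        reporters.append(2.0 ** (config.log2_base_mean
                                 + rng.normal(0.0, config.log2_base_sd, n_extra)[:, None]
                                 + rng.normal(0.0, config.reporter_sigma, (n_extra, C))))

    psms = pd.concat(frames, ignore_index=True)
    rep = np.vstack(reporters)

    # observed mass: truth + systematic ppm offset + ppm noise
    n_all = len(psms)
    ppm = config.calib_offset_ppm + rng.normal(0.0, config.mass_noise_ppm, n_all)
    true_mass = psms["theoretical_mass"].to_numpy() + psms["truth_delta_mass"].to_numpy()
    observed = true_mass * (1.0 + ppm * 1e-6)
    psms["observed_mass"] = observed
    psms["delta_mass"] = observed - psms["theoretical_mass"].to_numpy()
    psms["truth_ppm_error"] = ppm
    psms["spectrum_id"] = [f"s{i:07d}" for i in range(n_all)]
    # unmodified forms carry no localized site (0 would mean "N-terminus")
    site = psms["site_position"].to_numpy(dtype=float)
    site[site == 0] = np.nan
    psms["site_position"] = pd.Series(site).astype("Int64")

    for c in range(C):
        psms[f"reporter_{c + 1:02d}"] = rep[:, c]

    cols = ["spectrum_id", "peptide", "charge", "theoretical_mass", "observed_mass",
            "delta_mass", "score", "is_decoy", "protein", "site_position", "plex_id",
            "cys_tag_mass"]
    cols += [f"reporter_{c + 1:02d}" for c in range(C)]
    cols += ["truth_label", "truth_pepform", "truth_wave", "truth_delta_mass",
             "truth_ppm_error"]
    assert design is not None
    return psms[cols]


def simulate_experiment(config: SimConfig):
    """Convenience wrapper: (psms, design, truth, mod list, categories)."""
    truth = generate_ground_truth(config)
    psms = simulate_psm_table(truth, config)
    return psms, make_design(config), truth, default_mod_list(), truth.categories
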