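"""Synthetic study-data generator.

Emulates the structure of the dominance study's raw inputs so that every
downstream stage is testable without any external download:

* a 40-array two-color microarray experiment over five female groups
  (DF = dominant foundress, SF = subordinate foundress, Q = queen,
  DW = dominant worker, SW = subordinate worker; eight wasps per group) laid
  out as a complete loop design with a dye swap, duplicate spots, planted
  group effects, flagged bad spots, and an intensity-dependent dye bias;
* colony-structured cuticular-hydrocarbon (CHC) concentration tables with a
  planted block of correlated "colony-phase" compounds;
* BLAST-style tabular hit files plus platform membership and significant-gene
  lists whose 2x2 overlap is drawn from a noncentral hypergeometric law.

Everything is driven by a single :class:`SimConfig` and is bit-reproducible
for a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

#: the five female behavioural groups, in canonical order
GROUPS = ("DF", "SF", "Q", "DW", "SW")

#: colony phase per group: founding-phase (-1) vs worker-phase (+1)
PHASE = {"DF": -1.0, "SF": -1.0, "Q": 1.0, "DW": 1.0, "SW": 1.0}

CY3, CY5 = "Cy3", "Cy5"


class DesignError(ValueError):
    """Raised for an invalid array-design request."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Microarray terms are on the log2 scale and mirror the generative model
    the differential-expression stage fits:
    ``log2(fg) = mu + gene + tau_group + a_array + d_dye + s_spot + eps``.
    CHC terms are on the log10 scale:
    ``log10(conc) = compound + group_effect + colony + eps``.
    """

    # experiment layout
    n_per_group: int = 8
    n_transcripts: int = 1000
    spots_per_transcript: int = 2

    # planted differential expression
    frac_de: float = 0.10
    effect_size: float = 1.0          # log2 units
    de_pattern: str = "single_group"  # or "phase"

    # microarray noise structure (log2 units)
    mu: float = 10.0
    sd_gene: float = 1.0
    sd_array: float = 0.3
    sd_dye: float = 0.1
    sd_spot: float = 0.15
    sd_resid: float = 0.4

    # raw-intensity model
    background_level: float = 175.0
    sd_background: float = 0.25       # lognormal sigma of background draws
    flag_frac: float = 0.01
    # polynomial coefficients (in centered A) of the additive dye bias on M
    dye_bias: tuple[float, float, float] = (0.1, -0.05, 0.02)

    # CHC model (log10 units)
    n_compounds: int = 18
    n_sig_compounds: int = 13
    n_phase_compounds: int = 5        # correlated phase-pattern block
    chc_effect: float = 0.35
    chc_mu: float = 1.5
    sd_compound: float = 0.5
    sd_colony: float = 0.15
    sd_resid_chc: float = 0.25
    below_detection_rate: float = 0.02
    colony_structure: str = "focal"   # DF/SF pairs + Q/DW/SW trios; or "pairs"

    # ortholog-overlap fixture
    universe_size: int = 3000
    n_sig_focal: int = 400
    n_sig_other: int = 440
    odds_ratio: float = 1.0

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = dict(
            n_per_group=self.n_per_group,
            n_transcripts=self.n_transcripts,
            spots_per_transcript=self.spots_per_transcript,
            n_compounds=self.n_compounds,
            universe_size=self.universe_size,
        )
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if not self.odds_ratio > 0:
            raise ValueError("odds_ratio must be > 0")
        if self.de_pattern not in ("single_group", "phase"):
            raise ValueError("de_pattern must be 'single_group' or 'phase'")
        if self.colony_structure not in ("focal", "pairs"):
            raise ValueError("colony_structure must be 'focal' or 'pairs'")
        if self.n_sig_focal > self.universe_size or self.n_sig_other > self.universe_size:
            raise ValueError("significant-list sizes cannot exceed the universe")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    # independent named substreams per stage, all derived from the one seed
    return np.random.default_rng([int(cfg.seed), stream])


# ---------------------------------------------------------------------------
# sample sheet and loop design
# ---------------------------------------------------------------------------

def make_sample_sheet(cfg: SimConfig) -> pd.DataFrame:
    """Wasp-level metadata for the five focal groups.

    Ovary activation scores and wing wear follow the focal-wasp selection
    criteria (dominants score 4, subordinate workers and foundresses score 1,
    dominant workers 2-3; foragers and old queens show wing wear).  Colony
    membership mirrors the focal structure: foundress pairs (DF+SF per
    founding nest) and worker-phase trios (Q+DW+SW per mature nest), or
    simple pairs when ``colony_structure == 'pairs'``.
    """
    # rows are emitted in interleaved group order (DF1, SF1, Q1, DW1, SW1,
    # DF2, ...) so that the default loop design pairs different groups on
    # every array: a loop that chains same-group samples would carry almost
    # no direct within-array information about group contrasts
    rows = []
    for i in range(cfg.n_per_group):
        for g in GROUPS:
            rows.append({"sample": f"{g}{i + 1}", "group": g})
    df = pd.DataFrame(rows)

    if cfg.colony_structure == "focal":
        colony = []
        for _, r in df.iterrows():
            idx = int(r["sample"][len(r["group"]):])
            if r["group"] in ("DF", "SF"):
                colony.append(f"F{idx:02d}")
            else:
                colony.append(f"W{idx:02d}")
        df["colony"] = colony
    else:  # pairs: two same-group wasps per nest
        df["colony"] = [
            f"N{j:02d}" for j in (np.arange(len(df)) // 2 + 1)
        ]

    score = {"DF": 4, "SF": 1, "Q": 4, "DW": 2, "SW": 1}
    wear = {"DF": 0, "SF": 1, "Q": 1, "DW": 0, "SW": 1}
    df["ovary_score"] = df["group"].map(score)
    # dominant workers occasionally reach score 3
    rng = _rng(cfg, 11)
    dw = df["group"] == "DW"
    df.loc[dw, "ovary_score"] = rng.choice([2, 3], size=int(dw.sum()), p=[0.7, 0.3])
    df["wing_wear"] = df["group"].map(wear)
    return df


def make_loop_design(samples) -> pd.DataFrame:
    """Complete loop design with a dye swap over an ordered sample list.

    Array ``t`` carries sample ``t`` on Cy3 and sample ``t + 1`` (cyclic) on
    Cy5, so every sample is hybridised on exactly two arrays with opposite
    labels and the design graph is one cycle: ``n`` samples need ``n`` arrays.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise DesignError("a loop design needs at least 2 samples")
    n = len(samples)
    width = max(2, len(str(n)))
    rows = []
    for t in range(n):
        arr = f"A{t + 1:0{width}d}"
        rows.append({"array": arr, "channel": CY3, "sample": samples[t]})
        rows.append({"array": arr, "channel": CY5, "sample": samples[(t + 1) % n]})
    return pd.DataFrame(rows)


def check_design(design: pd.DataFrame) -> None:
    """Validate the loop-design invariants; raise DesignError on violation."""
    per_sample = design.groupby("sample")["channel"].agg(list)
    for s, chans in per_sample.items():
        if sorted(chans) != [CY3, CY5]:
            raise DesignError(f"sample {s} does not appear once per dye")
    per_array = design.groupby("array")["sample"].nunique()
    if not (per_array == 2).all():
        raise DesignError("every array must carry exactly 2 distinct samples")


# ---------------------------------------------------------------------------
# microarray simulation
# ---------------------------------------------------------------------------

def _planted_effects(cfg: SimConfig, rng: np.random.Generator):
    """Choose DE transcripts and their group-effect vectors tau (log2)."""
    n = cfg.n_transcripts
    n_de = int(round(cfg.frac_de * n))
    de_idx = np.sort(rng.choice(n, size=n_de, replace=False))
    tau = np.zeros((n, len(GROUPS)))
    de_group = np.full(n, "", dtype=object)
    sign = np.zeros(n)
    phase_vec = np.array([PHASE[g] for g in GROUPS])
    for t in de_idx:
        s = float(rng.choice([-1.0, 1.0]))
        sign[t] = s
        if cfg.de_pattern == "single_group":
            g = int(rng.integers(len(GROUPS)))
            tau[t, g] = s * cfg.effect_size
            de_group[t] = GROUPS[g]
        else:
            tau[t] = s * cfg.effect_size / 2.0 * phase_vec
            de_group[t] = "phase"
    return de_idx, tau, de_group, sign


def simulate_microarray(cfg: SimConfig, design: pd.DataFrame | None = None):
    """Simulate spot-level two-channel intensities plus ground truth.

    Returns ``(spots, samples, truth)``: a GPR-like spot table (one row per
    array x spot with both channels), the sample sheet, and a truth table
    recording which transcripts carry a planted effect and which of the ten
    pairwise contrasts are truly non-null for each.
    """
    samples = make_sample_sheet(cfg)
    if design is None:
        design = make_loop_design(samples["sample"])
    check_design(design)
    rng = _rng(cfg, 1)

    transcripts = np.array([f"PM{i + 1:04d}" for i in range(cfg.n_transcripts)])
    group_of = dict(zip(samples["sample"], samples["group"]))
    gi = {g: i for i, g in enumerate(GROUPS)}

    de_idx, tau, de_group, sign = _planted_effects(cfg, rng)

    gene = cfg.mu + rng.normal(0.0, cfg.sd_gene, cfg.n_transcripts)
    arrays = design["array"].unique()
    a_eff = dict(zip(arrays, rng.normal(0.0, cfg.sd_array, arrays.shape[0])))
    d_eff = {CY3: rng.normal(0.0, cfg.sd_dye), CY5: rng.normal(0.0, cfg.sd_dye)}
    s_eff = rng.normal(0.0, cfg.sd_spot, (cfg.n_transcripts, cfg.spots_per_transcript))

    # channel -> sample per array
    ch_sample = design.pivot(index="array", columns="channel", values="sample")

    n_t, n_s, n_a = cfg.n_transcripts, cfg.spots_per_transcript, arrays.shape[0]
    base = gene[:, None, None] + s_eff[:, :, None] + np.array(
        [a_eff[a] for a in arrays]
    )[None, None, :]

    log2fg = {}
    for ch in (CY3, CY5):
        gidx = np.array([gi[group_of[ch_sample.loc[a, ch]]] for a in arrays])
        sig = base + tau[:, gidx][:, None, :] + d_eff[ch]
        sig = sig + rng.normal(0.0, cfg.sd_resid, (n_t, n_s, n_a))
        log2fg[ch] = sig

    # intensity-dependent dye bias applied symmetrically around A
    A = 0.5 * (log2fg[CY3] + log2fg[CY5])
    c0, c1, c2 = cfg.dye_bias
    Ac = A - A.mean()
    bias = c0 + c1 * Ac + c2 * Ac**2
    log2fg[CY5] = log2fg[CY5] + bias / 2.0
    log2fg[CY3] = log2fg[CY3] - bias / 2.0

    bg = {
        ch: cfg.background_level
        * np.exp(rng.normal(0.0, cfg.sd_background, (n_t, n_s, n_a)))
        for ch in (CY3, CY5)
    }
    fg = {ch: 2.0 ** log2fg[ch] + bg[ch] for ch in (CY3, CY5)}
    flags = (rng.random((n_t, n_s, n_a)) < cfg.flag_frac).astype(int)

    t_ix, s_ix, a_ix = np.meshgrid(
        np.arange(n_t), np.arange(n_s), np.arange(n_a), indexing="ij"
    )
    spots = pd.DataFrame(
        {
            "array": arrays[a_ix.ravel()],
            "spot": np.char.add(
                np.char.add(transcripts[t_ix.ravel()], "_s"),
                (s_ix.ravel() + 1).astype(str),
            ),
            "transcript": transcripts[t_ix.ravel()],
            "fg_cy3": fg[CY3].ravel(),
            "bg_cy3": bg[CY3].ravel(),
            "fg_cy5": fg[CY5].ravel(),
            "bg_cy5": bg[CY5].ravel(),
            "flag": flags.ravel(),
        }
    )
    spots = spots.sort_values(["array", "spot"], kind="stable").reset_index(drop=True)

    truth = pd.DataFrame({"transcript": transcripts, "is_de": False})
    truth.loc[de_idx, "is_de"] = True
    truth["de_group"] = de_group
    truth["sign"] = sign
    for g1, g2 in itertools.combinations(GROUPS, 2):
        diff = tau[:, gi[g1]] - tau[:, gi[g2]]
        truth[f"de_{g1}_vs_{g2}"] = diff != 0.0
    return spots, samples, truth


# ---------------------------------------------------------------------------
# cuticular hydrocarbons
# ---------------------------------------------------------------------------

def simulate_chc(cfg: SimConfig):
    """Simulate an absolute-concentration CHC table with colony structure.

    Returns ``(compounds, samples, truth, metadata)``.  Of the
    ``n_sig_compounds`` planted compounds, ``n_phase_compounds`` form a
    correlated block sharing the colony-phase pattern (low in foundresses,
    high in queens/workers); the rest get independent random group-effect
    vectors.  Values below the per-compound detection limit (the
    ``below_detection_rate`` quantile) are reported as exact zeros.
    """
    if cfg.n_sig_compounds > cfg.n_compounds:
        raise ValueError("n_sig_compounds cannot exceed n_compounds")
    if cfg.n_phase_compounds > cfg.n_sig_compounds:
        raise ValueError("n_phase_compounds cannot exceed n_sig_compounds")
    samples = make_sample_sheet(cfg)
    rng = _rng(cfg, 2)
    n_c = cfg.n_compounds
    compounds = np.array([f"chc{i + 1:02d}" for i in range(n_c)])

    sig_idx = np.sort(rng.choice(n_c, size=cfg.n_sig_compounds, replace=False))
    phase_idx = np.sort(rng.choice(sig_idx, size=cfg.n_phase_compounds, replace=False))
    phase_vec = np.array([PHASE[g] for g in GROUPS])

    effects = np.zeros((n_c, len(GROUPS)))
    pattern = np.full(n_c, "none", dtype=object)
    for c in sig_idx:
        if c in phase_idx:
            scale = rng.uniform(0.8, 1.2)
            effects[c] = cfg.chc_effect / 2.0 * scale * phase_vec
            pattern[c] = "phase"
        else:
            v = rng.normal(0.0, 1.0, len(GROUPS))
            v -= v.mean()
            v *= cfg.chc_effect / max(np.abs(v).max(), 1e-12)
            effects[c] = v
            pattern[c] = "random"

    comp_mu = cfg.chc_mu + rng.normal(0.0, cfg.sd_compound, n_c)
    colonies = samples["colony"].unique()
    col_eff = dict(zip(colonies, rng.normal(0.0, cfg.sd_colony, colonies.shape[0])))
    gi = {g: i for i, g in enumerate(GROUPS)}

    rows = []
    for _, w in samples.iterrows():
        g = gi[w["group"]]
        log10 = (
            comp_mu
            + effects[:, g]
            + col_eff[w["colony"]]
            + rng.normal(0.0, cfg.sd_resid_chc, n_c)
        )
        for c in range(n_c):
            rows.append(
                {
                    "wasp": w["sample"],
                    "group": w["group"],
                    "colony": w["colony"],
                    "compound": compounds[c],
                    "concentration": 10.0 ** log10[c],
                }
            )
    table = pd.DataFrame(rows)

    # below-detection censoring at the per-compound rate quantile
    if cfg.below_detection_rate > 0:
        for c in compounds:
            m = table["compound"] == c
            lim = table.loc[m, "concentration"].quantile(cfg.below_detection_rate)
            table.loc[m & (table["concentration"] < lim), "concentration"] = 0.0

    truth = pd.DataFrame(
        {
            "compound": compounds,
            "is_sig": np.isin(np.arange(n_c), sig_idx),
            "pattern": pattern,
        }
    )
    chain = np.linspace(25, 40, n_c).round().astype(int)
    metadata = pd.DataFrame(
        {
            "compound": compounds,
            "name": [f"synthetic hydrocarbon C{cl}" for cl in chain],
            "retention_time": np.linspace(27.6, 56.7, n_c).round(1),
            "chain_length": chain,
            "molecular_weight": (chain * 14 + 2),
        }
    )
    return table, samples, truth, metadata


# ---------------------------------------------------------------------------
# ortholog-overlap fixture
# ---------------------------------------------------------------------------

def simulate_ortholog_lists(cfg: SimConfig) -> dict:
    """BLAST-style hit table plus platform and significant-gene lists.

    The 2x2 overlap of the significant lists over the mapped, shared universe
    is drawn from Fisher's noncentral hypergeometric distribution with the
    configured odds ratio.  The hit table deliberately contains decoy hits
    above the e-value cutoff, tied best hits (resolved by bit score, then by
    subject id) and queries whose subjects are absent from the other
    platform, so downstream filtering and tie-breaking are exercised.
    """
    rng = _rng(cfg, 3)
    N = cfg.universe_size
    queries = np.array([f"PM{i + 1:05d}" for i in range(N)])
    subjects = np.array([f"GB{i + 1:05d}" for i in range(N)])

    if np.isinf(cfg.odds_ratio):
        n11 = min(cfg.n_sig_focal, cfg.n_sig_other)
    elif cfg.odds_ratio == 1.0:
        n11 = int(stats.hypergeom(N, cfg.n_sig_other, cfg.n_sig_focal).rvs(random_state=rng))
    else:
        n11 = int(
            stats.nchypergeom_fisher(
                N, cfg.n_sig_other, cfg.n_sig_focal, cfg.odds_ratio
            ).rvs(random_state=rng)
        )

    other_sig_idx = rng.choice(N, size=cfg.n_sig_other, replace=False)
    rest = np.setdiff1d(np.arange(N), other_sig_idx)
    focal_in = rng.choice(other_sig_idx, size=n11, replace=False)
    focal_out = rng.choice(rest, size=cfg.n_sig_focal - n11, replace=False)
    focal_sig_idx = np.concatenate([focal_in, focal_out])

    n_extra = max(2, N // 20)
    off_platform_q = np.array([f"PMX{i + 1:04d}" for i in range(n_extra)])
    off_platform_s = np.array([f"OF{i + 1:05d}" for i in range(n_extra)])
    weak_q = np.array([f"PMW{i + 1:04d}" for i in range(n_extra)])

    hits = []

    def _hit(q, s, evalue, bits):
        hits.append(
            dict(
                qseqid=q, sseqid=s, pident=round(rng.uniform(40, 95), 2),
                length=int(rng.integers(60, 400)), mismatch=int(rng.integers(0, 40)),
                gapopen=int(rng.integers(0, 5)), qstart=1, qend=100, sstart=1,
                send=100, evalue=evalue, bitscore=bits,
            )
        )

    for i, (q, s) in enumerate(zip(queries, subjects)):
        u = rng.uniform(6.0, 30.0)
        best_e = 10.0 ** (-u)
        best_bits = round(50.0 + 2.0 * u + rng.normal(0, 2), 1)
        _hit(q, s, best_e, best_bits)
        r = rng.random()
        if r < 0.20:  # worse secondary hit to a different subject
            _hit(q, subjects[(i + 7) % N], best_e * 10 ** rng.uniform(2, 6),
                 round(best_bits - rng.uniform(5, 30), 1))
        if r < 0.10:  # decoy above the cutoff
            _hit(q, subjects[(i + 13) % N], 10.0 ** rng.uniform(-4, 0),
                 round(rng.uniform(20, 40), 1))
        if 0.10 <= r < 0.15:  # tie on e-value, loses on bit score
            _hit(q, f"ZZTIE{i:05d}", best_e, round(best_bits - 1.0, 1))
        if 0.15 <= r < 0.17:  # full tie, loses lexicographically
            _hit(q, f"ZZTIE{i:05d}", best_e, best_bits)

    for q, s in zip(off_platform_q, off_platform_s):
        u = rng.uniform(6.0, 30.0)
        _hit(q, s, 10.0 ** (-u), round(50 + 2 * u, 1))
    for q in weak_q:
        _hit(q, subjects[int(rng.integers(N))], 10.0 ** rng.uniform(-4, -1),
             round(rng.uniform(20, 40), 1))

    blast = pd.DataFrame(hits)
    focal_platform = set(queries) | set(off_platform_q) | set(weak_q)
    other_platform = set(subjects) | {f"EX{i + 1:05d}" for i in range(n_extra)}
    focal_sig = {queries[i] for i in focal_sig_idx} | {"PMNOTONARRAY01"}
    other_sig = {subjects[i] for i in other_sig_idx} | {"GBNOTONARRAY01"}

    truth = dict(
        n11=n11,
        n10=cfg.n_sig_focal - n11,
        n01=cfg.n_sig_other - n11,
        n00=N - cfg.n_sig_focal - cfg.n_sig_other + n11,
        universe=N,
    )
    return dict(
        blast=blast,
        focal_platform=focal_platform,
        other_platform=other_platform,
        focal_sig=focal_sig,
        other_sig=other_sig,
        truth=truth,
    )
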