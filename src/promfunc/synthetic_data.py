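"""Ground-truthed synthetic inputs for every stage of the pipeline.

The generator emulates the shape of a promoter-mutagenesis reporter
screen: ~1 kb promoter fragments with a motif instance planted per
construct, ChIP-seq-like peaks whose summits jitter around the planted
site, a conservation track elevated over functional sites, and replicate
luminosity tables (3 preps x 3 transfections per allele per cell line)
with multiplicative activation/repression effects plus negative-control
and unbound-site construct classes.  All randomness flows from a single
seed; the emitted truth table is the test oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .class_comparison import PromoterAnnotation
from .motif_core import PWM, build_pwm, reverse_complement, sample_site
from .site_prediction import PeakRegion

CELL_LINES = ("K562", "HCT116", "HT1080", "HepG2")


@dataclass
class SimulationConfig:
    """Stated world for the synthetic screen.

    Defaults mirror the published screen's shape: 455 constructs assayed in
    four cell lines with per-cell-line functional fractions 49/38/36/39%,
    repression in a third of functional sites, 12 negative controls and 23
    unbound PWM matches (30% functional) assayed in K562 only, and plates
    carrying four positive and four negative control transfections.
    """

    seed: int
    n_promoters: int = 455
    promoter_length: int = 1000
    gc_content: float = 0.41
    pwm_width: int = 12
    pwm_concentration: float = 0.05
    cell_lines: tuple[str, ...] = CELL_LINES
    functional_fractions: tuple[float, ...] = (0.49, 0.38, 0.36, 0.39)
    repressing_fraction: float = 1.0 / 3.0
    effect_range: tuple[float, float] = (0.5, 2.0)
    noise_cv: float = 0.2
    wells_per_plate: int = 96
    n_pos_ctrl_wells: int = 4
    n_neg_ctrl_wells: int = 4
    summit_sigma: float = 20.0
    peak_halfwidth: int = 150
    conservation_baseline_sd: float = 0.5
    conservation_elevation: float = 1.5
    tss_offset_from_end: int = 200
    translational_start_offset: int = 120
    activating_sigma: float = 30.0
    repressing_sigma: float = 10.0
    nonfunctional_range: tuple[int, int] = (-600, -50)
    homotypic_distribution: tuple[float, ...] = (0.85, 0.11, 0.04)
    n_negative_controls: int = 12
    n_unbound: int = 23
    unbound_functional_fraction: float = 0.30
    plate_factor_sigma: float = 0.3
    baseline_sigma: float = 0.5

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for f in (*self.functional_fractions, self.repressing_fraction,
                  self.unbound_functional_fraction, self.gc_content):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {f} outside [0, 1]")
        if self.promoter_length <= 0 or self.pwm_width <= 0:
            raise ValueError("lengths must be positive")
        if len(self.functional_fractions) != len(self.cell_lines):
            raise ValueError("one functional fraction per cell line required")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_dict(self) -> dict:
        return asdict(self)


def random_pwm(
    width: int,
    rng: np.random.Generator,
    concentration: float = 0.05,
    n_observations: int = 100,
    name: str = "TF1",
) -> PWM:
    """Random informative PWM: per-position probabilities from a symmetric
    Dirichlet (low concentration -> near-deterministic positions), scaled to
    a count matrix."""
    probs = rng.dirichlet(np.full(4, concentration), size=width)
    counts = np.maximum(probs * n_observations, 0.0)
    return build_pwm(counts, pseudocount=0.5, name=name)


def generate_promoters(config: SimulationConfig, rng=None) -> dict[str, PromoterAnnotation]:
    """I.i.d. background promoter fragments at the configured GC content.

    The TSS sits near the transcript-orientation 3' end of the fragment
    (most of the clone is upstream promoter), the translational start
    downstream of the TSS.  Fragment strand alternates so both orientations
    are exercised.  Conservation tracks start at zero and are filled in by
    :func:`plant_sites`.
    """
    rng = rng or config.rng()
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    L = config.promoter_length
    anns: dict[str, PromoterAnnotation] = {}
    for i in range(config.n_promoters):
        seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=L, p=p)])
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            tss = L - config.tss_offset_from_end
            ts = min(L - 1, tss + config.translational_start_offset)
        else:
            tss = config.tss_offset_from_end
            ts = max(0, tss - config.translational_start_offset)
        anns[f"prom_{i:04d}"] = PromoterAnnotation(
            promoter_id=f"prom_{i:04d}", chrom=f"prom_{i:04d}", strand=strand,
            tss=tss, translational_start=ts, sequence=seq,
            conservation=np.zeros(L),
        )
    return anns


def _noise_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _place_center(ann: PromoterAnnotation, direction: str, functional: bool,
                  config: SimulationConfig, rng: np.random.Generator) -> int:
    """Transcript-oriented placement: activating sites near the TSS,
    repressing sites at/near the translational start, unverified sites
    scattered upstream."""
    if not functional:
        delta = rng.uniform(*config.nonfunctional_range)
    elif direction == "repressing":
        base = (ann.translational_start - ann.tss) * (1 if ann.strand == "+" else -1)
        delta = base + rng.normal(0, config.repressing_sigma)
    else:
        delta = rng.normal(0, config.activating_sigma)
    center = ann.tss + (delta if ann.strand == "+" else -delta)
    half = config.pwm_width / 2
    return int(np.clip(center, half + 1, len(ann.sequence) - half - 1))


def plant_sites(
    annotations: dict[str, PromoterAnnotation],
    pwm: PWM,
    config: SimulationConfig,
    rng=None,
):
    """Plant one primary motif instance per promoter; emit peaks,
    conservation tracks and the ground-truth table.

    Returns ``(annotations, truth, peaks)``: modified annotations (sequence
    with planted sites, conservation = Gaussian baseline + elevation over
    functional sites), a truth DataFrame (one row per construct with planted
    offset/strand, per-cell-line functional status, direction, effect sizes
    and homotypic instance count), and one PeakRegion per construct whose
    summit jitters around the planted site center.
    """
    rng = rng or config.rng()
    W = pwm.width
    if W >= config.promoter_length:
        raise ValueError("PWM width must be smaller than promoter length")
    truth_rows = []
    peaks = []
    out: dict[str, PromoterAnnotation] = {}

    # realize the configured per-cell-line functional fractions exactly
    # (stratified assignment): the config states the ground truth, so the
    # truth table carries no binomial noise around it
    n = len(annotations)
    functional_matrix = np.zeros((n, len(config.cell_lines)), dtype=bool)
    for j, frac in enumerate(config.functional_fractions):
        k = int(round(frac * n))
        functional_matrix[rng.choice(n, size=k, replace=False), j] = True

    for i, ann in enumerate(annotations.values()):
        L = len(ann.sequence)
        functional = functional_matrix[i]
        any_func = bool(functional.any())
        direction = "none"
        if any_func:
            direction = ("repressing"
                         if rng.random() < config.repressing_fraction else "activating")
        effects = np.where(functional, rng.uniform(*config.effect_range,
                                                   size=len(config.cell_lines)), 0.0)

        center = _place_center(ann, direction, any_func, config, rng)
        start = center - W // 2
        site_strand = "+" if rng.random() < 0.5 else "-"
        site_seq = sample_site(pwm, rng)
        planted = site_seq if site_strand == "+" else reverse_complement(site_seq)
        seq = ann.sequence[:start] + planted + ann.sequence[start + W:]

        # homotypic extras: total instance count drawn from the configured law
        n_instances = 1 + int(rng.choice(len(config.homotypic_distribution),
                                         p=config.homotypic_distribution))
        extra_starts = []
        for _ in range(n_instances - 1):
            for _attempt in range(1000):
                s = int(rng.integers(0, L - W + 1))
                if abs(s - start) >= W and all(abs(s - e) >= W for e in extra_starts):
                    extra_starts.append(s)
                    seq = seq[:s] + sample_site(pwm, rng) + seq[s + W:]
                    break
            else:
                raise RuntimeError("could not place homotypic copy after 1000 attempts")

        cons = rng.normal(0.0, config.conservation_baseline_sd, size=L)
        if any_func and config.conservation_elevation:
            cons[start : start + W] += config.conservation_elevation

        peak_start = max(0, center - config.peak_halfwidth)
        peak_end = min(L, center + config.peak_halfwidth)
        summit = int(np.clip(center + rng.normal(0, config.summit_sigma),
                             peak_start, peak_end - 1)) - peak_start
        peaks.append(PeakRegion(ann.promoter_id, peak_start, peak_end, summit,
                                float(rng.uniform(0, 0.04))))

        out[ann.promoter_id] = PromoterAnnotation(
            ann.promoter_id, ann.chrom, ann.strand, ann.tss,
            ann.translational_start, seq, cons,
        )
        row = {
            "construct_id": ann.promoter_id,
            "tf": pwm.name,
            "exp_class": "tfbs",
            "site_start": start,
            "site_end": start + W,
            "site_strand": site_strand,
            "extra_site_starts": ",".join(map(str, sorted(extra_starts))),
            "direction": direction,
            "homotypic_instances": n_instances,
            "tss": ann.tss,
            "translational_start": ann.translational_start,
            "promoter_strand": ann.strand,
        }
        for cl, f, e in zip(config.cell_lines, functional, effects):
            row[f"functional_{cl}"] = bool(f)
            row[f"effect_{cl}"] = float(e)
        truth_rows.append(row)
    return out, pd.DataFrame(truth_rows), peaks


def control_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Truth rows for negative controls (never functional) and unbound PWM
    matches (functional at a configurable low rate), both K562-only."""
    rows = []
    primary = config.cell_lines[0]
    for i in range(config.n_negative_controls):
        row = {"construct_id": f"negctrl_{i:02d}", "tf": "none", "exp_class": "neg_ctrl",
               "direction": "none"}
        for cl in config.cell_lines:
            row[f"functional_{cl}"] = False
            row[f"effect_{cl}"] = 0.0
        rows.append(row)
    for i in range(config.n_unbound):
        functional = rng.random() < config.unbound_functional_fraction
        direction = "none"
        effect = 0.0
        if functional:
            direction = ("repressing"
                         if rng.random() < config.repressing_fraction else "activating")
            effect = float(rng.uniform(*config.effect_range))
        row = {"construct_id": f"unbound_{i:02d}", "tf": "unbound", "exp_class": "unbound",
               "direction": direction}
        for cl in config.cell_lines:
            row[f"functional_{cl}"] = functional if cl == primary else False
            row[f"effect_{cl}"] = effect if cl == primary else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_luminosity(
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng=None,
    include_controls: bool = True,
) -> pd.DataFrame:
    """Replicate luminosity table with known functional structure.

    Every construct gets 9 WT + 9 MT wells per assayed cell line (3 preps x
    3 transfections).  A WT well is ``baseline x plate factor x lognormal
    noise``; the matching MT well is additionally scaled by ``2^(-effect)``
    for activating sites and ``2^(+effect)`` for repressing ones.  Plates
    are filled sequentially and each carries four positive and four
    negative control transfections, included in the normalization pool.
    Constructs of class 'neg_ctrl' and 'unbound' are appended (first cell
    line only) when ``include_controls`` is set.
    """
    rng = rng or config.rng()
    sigma = _noise_sigma(config.noise_cv)

    if include_controls:
        truth = pd.concat([truth, control_truth(config, rng)], ignore_index=True)

    baselines = {
        c: float(rng.lognormal(0.0, config.baseline_sigma))
        for c in truth["construct_id"]
    }

    # enumerate experimental wells: WT/MT pairs stay adjacent so they mostly
    # share a plate, as in a paired transfection layout
    wells = []
    for _, row in truth.iterrows():
        assayed = (config.cell_lines if row["exp_class"] == "tfbs"
                   else config.cell_lines[:1])
        for cl in assayed:
            effect = row[f"effect_{cl}"]
            signed = (-effect if row["direction"] == "activating" else effect)
            for prep in (1, 2, 3):
                for txn in (1, 2, 3):
                    wells.append((row["construct_id"], "WT", cl, prep, txn,
                                  row["tf"], row["exp_class"], 0.0))
                    wells.append((row["construct_id"], "MT", cl, prep, txn,
                                  row["tf"], row["exp_class"], signed))

    n_exp_per_plate = config.wells_per_plate - config.n_pos_ctrl_wells - config.n_neg_ctrl_wells
    rows = []
    n_plates = math.ceil(len(wells) / n_exp_per_plate)
    for plate in range(n_plates):
        plate_id = f"plate_{plate:04d}"
        plate_factor = float(rng.lognormal(0.0, config.plate_factor_sigma))
        chunk = wells[plate * n_exp_per_plate : (plate + 1) * n_exp_per_plate]
        for construct, allele, cl, prep, txn, tf, exp_class, signed in chunk:
            noise = rng.lognormal(-sigma * sigma / 2, sigma)
            raw = baselines[construct] * plate_factor * noise * 2.0 ** signed
            rows.append((construct, allele, cl, prep, txn, plate_id, raw, tf, exp_class))
        ctrl_cell = chunk[0][2] if chunk else config.cell_lines[0]
        for k in range(config.n_pos_ctrl_wells):
            noise = rng.lognormal(-sigma * sigma / 2, sigma)
            rows.append((f"posctrl", "pos_ctrl", ctrl_cell, 1, k + 1, plate_id,
                         10.0 * plate_factor * noise, "none", "plate_ctrl"))
        for k in range(config.n_neg_ctrl_wells):
            noise = rng.lognormal(-sigma * sigma / 2, sigma)
            rows.append((f"negwell", "neg_ctrl", ctrl_cell, 1, k + 1, plate_id,
                         0.05 * plate_factor * noise, "none", "plate_ctrl"))
    return pd.DataFrame(
        rows,
        columns=["construct_id", "allele", "cell_line", "prep_rep", "txn_rep",
                 "plate_id", "raw", "tf", "exp_class"],
    )


def run_screen(config: SimulationConfig, alpha: float = 0.025) -> dict:
    """End-to-end synthetic screen: promoters -> planted sites -> luminosity
    -> plate normalization -> Welch tests -> global BH -> calls + summary.

    Returns annotations, pwm, truth, peaks, luminosity, calls and summary.
    """
    from .reporter_stats import analyze, summarize_calls

    rng = config.rng()
    pwm = random_pwm(config.pwm_width, rng, config.pwm_concentration)
    anns = generate_promoters(config, rng)
    anns, truth, peaks = plant_sites(anns, pwm, config, rng)
    truth = pd.concat([truth, control_truth(config, rng)], ignore_index=True)
    lum = simulate_luminosity(truth, config, rng, include_controls=False)
    calls = analyze(lum, alpha=alpha)
    summary = summarize_calls(calls[calls["exp_class"] == "tfbs"],
                              n_cell_lines=len(config.cell_lines))
    return {
        "config": config, "pwm": pwm, "annotations": anns, "truth": truth,
        "peaks": peaks, "luminosity": lum, "calls": calls, "summary": summary,
    }
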