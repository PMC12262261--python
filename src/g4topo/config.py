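"""Pipeline configuration.

Every fixed constant used downstream lives here so a run is described by a
single object: the G4Hunter window and threshold, consensus-motif loop
bounds, control-matching tolerance, methylation cut-points, mutation window
half-width, allele-frequency floor, profile bin counts, flank width,
bootstrap replicates, the proximal radius for peak summaries, the pangenome
conservation threshold, and the chromosomes excluded from mutation and
conservation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class PipelineConfig:
    # G4Hunter
    window: int = 25
    score_threshold: float = 1.5
    refine: str = "none"  # {"none", "trim-to-runs"}
    # consensus motif
    min_run: int = 3
    loop_min: int = 1
    loop_max: int = 7
    # binning / enrichment
    bin_size: int = 100_000
    train_bin_size: int = 2_000_000
    candidate_bin_sizes: tuple[int, ...] = (500_000, 1_000_000, 2_000_000, 4_000_000)
    cv_folds: int = 10
    # matched controls
    control_tolerance: float = 0.10
    controls_per_g4: int = 2
    max_shift_attempts: int = 10_000
    anchors_per_g4: int = 5
    # methylation
    hypo_cut: float = 0.2
    hyper_cut: float = 0.8
    dirichlet_tol: float = 1e-4
    dirichlet_window: int = 100
    dirichlet_max_steps: int = 200_000
    # mutations
    mutation_half_width: int = 50
    af_min: float = 0.05
    small_indel_max: int = 50
    # microstructure profile
    run_bins: int = 20
    loop_bins: int = 30
    flank: int = 500
    # peaks
    bootstrap_n: int = 1000
    proximal_radius: int = 250
    peak_half_window: int = 1000
    # pangenome
    conservation_threshold: float = 50.0
    conserved_rule: str = "any"  # {"any", "mean", "all"}
    share_bins: int = 2000
    haplotype_total: int = 88
    # global
    exclude_chroms: tuple[str, ...] = ("chrY",)
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = {
            k: v
            for k, v in asdict(self).items()
            if isinstance(v, (int, float)) and not isinstance(v, bool)
        }
        for name in (
            "window", "score_threshold", "min_run", "loop_min", "loop_max",
            "bin_size", "train_bin_size", "cv_folds", "control_tolerance",
            "controls_per_g4", "max_shift_attempts", "hypo_cut", "hyper_cut",
            "dirichlet_tol", "mutation_half_width", "af_min", "small_indel_max",
            "run_bins", "loop_bins", "flank", "bootstrap_n", "proximal_radius",
            "peak_half_window", "conservation_threshold", "share_bins",
            "haplotype_total",
        ):
            if numeric[name] <= 0:
                raise ValueError(f"config parameter {name} must be strictly positive")
        if not (0 < self.hypo_cut < self.hyper_cut < 1):
            raise ValueError("methylation cut-points must satisfy 0 < hypo < hyper < 1")
        if self.refine not in ("none", "trim-to-runs"):
            raise ValueError(f"unknown refine mode {self.refine!r}")
        if self.conserved_rule not in ("any", "mean", "all"):
            raise ValueError(f"unknown conserved_rule {self.conserved_rule!r}")


DEFAULT_CONFIG = PipelineConfig()
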