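"""Generate the synthetic study inputs with known ground truth.

Emulates the study design: a treatment gammaH2AX ChIP track with planted
broad DSB domains and point binding sites over Poisson background, an input
control track, and the qPCR Ct tables. Coverage tracks are large, so the
fixture files land under scratch/fixtures; the truth table and manifest are
copied to results/ for inspection.
"""

import shutil
from pathlib import Path

from gammafoci import (
    RunConfig,
    random_truth,
    simulate_chip_qpcr,
    simulate_ct_table,
    simulate_tracks,
    track_stats,
    write_fixtures,
)

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 0) -> None:
    cfg = RunConfig(seed=seed)
    genome = cfg.genome()
    truth = random_truth(
        genome, n_domains=cfg.n_domains,
        domain_length_range=(cfg.domain_length_min, cfg.domain_length_max),
        domain_fold=cfg.domain_fold, n_sites=cfg.n_sites,
        site_half_width=cfg.site_half_width, site_fold=cfg.site_fold,
        background_rate=cfg.background_rate, seed=cfg.seed,
        min_separation=cfg.min_separation,
    )
    treatment, control = simulate_tracks(genome, truth, cfg.library_ratio)
    expression_ct = simulate_ct_table(
        cfg.expression_design, cfg.reference_genes, replicates=cfg.ct_replicates,
        noise_sd=cfg.ct_noise_sd, seed=cfg.seed,
    )
    chip_ct = simulate_chip_qpcr(
        cfg.chip_percent_input, input_fraction=cfg.input_fraction,
        replicates=cfg.ct_replicates, noise_sd=cfg.chip_noise_sd, seed=cfg.seed,
    )
    fixdir = ROOT / "scratch" / "fixtures"
    manifest = write_fixtures(fixdir, genome, truth, treatment, control,
                              expression_ct, chip_ct)

    outdir = ROOT / "results"
    outdir.mkdir(exist_ok=True)
    shutil.copy(fixdir / "truth.tsv", outdir / "truth.tsv")
    cfg.to_yaml(outdir / "run_config.yaml")

    stats = track_stats(treatment)
    print(f"wrote {len(manifest)} fixture files to {fixdir}")
    print(f"planted {len(truth.domains)} fold-{cfg.domain_fold} domains and "
          f"{len(truth.sites)} fold-{cfg.site_fold} sites")
    print(f"treatment track: {stats.total:.0f} tags, {stats.mean_per_bin:.2f}/bin "
          f"over {stats.n_bins} bins")


if __name__ == "__main__":
    main()
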