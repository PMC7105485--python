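import numpy as np
import pandas as pd
import pytest

from gwaspipe import scores, synth


@pytest.fixture(scope="session")
def ea_cohort():
    """Small East Asian cohort under the default generative model.

    Prevalence is raised to 0.01 to keep quota sampling cheap; odds ratios
    are invariant to the ascertainment so recovery tests are unaffected.
    """
    spec = synth.east_asian_spec(n_cases=1500, n_controls=3000, prevalence=0.01, seed=11)
    return synth.simulate_case_control(spec, batch_size=200_000)


@pytest.fixture(scope="session")
def ea_scored(ea_cohort):
    definition = scores.load_score_definition("east_asian")
    scored = scores.compute_grs(ea_cohort.genotypes, definition)
    pheno = ea_cohort.phenotypes.copy()
    pheno["grs_raw"] = scored["grs_raw"]
    pheno["grs"] = scored["grs"]
    cohort = synth.Cohort(
        genotypes=ea_cohort.genotypes,
        phenotypes=pheno,
        effect_alleles=ea_cohort.effect_alleles,
        haplotypes=ea_cohort.haplotypes,
    )
    return cohort


@pytest.fixture(scope="session")
def drb1_cohort():
    """Phased classical-allele cohort with residue-level risk at two positions."""
    rng = np.random.default_rng(7)
    freqs = {
        "DRB1*1501": 0.08,
        "DRB1*0301": 0.10,
        "DRB1*0901": 0.30,
        "DRB1*0405": 0.22,
        "DRB1*0701": 0.30,
    }
    n = 4000
    haps = synth.simulate_allele_haplotypes(freqs, n, rng)
    table = synth.default_drb1_residues()
    residues = synth.assign_residues(haps, table)
    # per-allele risk chosen so that no single position captures the signal:
    # position 13 cannot separate 0901/0701 (both Gly), position 71 cannot
    # separate 0901/0405 (both Arg), position 74 cannot separate 1501/0405
    # (both Ala) -- exactly two positions are needed
    allele_lp = {"DRB1*1501": 1.3, "DRB1*0301": 0.0, "DRB1*0901": 0.0,
                 "DRB1*0405": 0.8, "DRB1*0701": 0.6}
    lp = sum(w * (haps == a).sum(axis=1) for a, w in allele_lp.items()) - 2.2
    status = (rng.random(n) < 1.0 / (1.0 + np.exp(-lp))).astype(int)
    allele_dosages = pd.DataFrame(
        {a: (haps == a).sum(axis=1).astype(float) for a in freqs}
    )
    return {
        "haplotypes": haps,
        "residues": residues,
        "status": status,
        "allele_dosages": allele_dosages,
        "freqs": freqs,
    }
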