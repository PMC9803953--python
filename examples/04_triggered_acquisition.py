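"""Simulate diagnostic-ion-triggered stepped-HCD acquisition.

Labeled peptides fragment poorly at the base collision energy but yield the
probe's low-mass diagnostic ions; when a survey MS2 contains one of the two
trigger ions (194.05822 or 247.08477 m/z), three extra scans at 28/32/36%
NCE are appended.  The identification gain is the extra labeled peptides the
stepped scans recover.
"""

from phosid import default_probe
from phosid.acquisition import (AcquisitionMethod, SyntheticRunSpec,
                                build_roster, evaluate_trigger_gain,
                                simulate_run)
from phosid.synthetic import make_proteome

probe = default_probe()
proteome = make_proteome(20, seed=44)
roster = build_roster(proteome, probe, n_peptides=40, labeled_fraction=0.4,
                      seed=44)
spec = SyntheticRunSpec(
    seed=15, peptides=roster,
    frag_eff_labeled={28.0: 0.02, 32.0: 0.50, 36.0: 0.60},
    nl_yield={28.0: 0.02, 32.0: 0.70, 36.0: 0.80},
    di_yield={28.0: 0.20, 32.0: 0.90, 36.0: 0.95})
method = AcquisitionMethod(trigger_ions=tuple(probe.trigger_ions))

spectra, truth = simulate_run(spec, method, probe)
n_stepped = int((truth.provenance == "triggered_step").sum())
print(f"scans acquired:     {len(spectra)} ({n_stepped} triggered stepped)")

gain = evaluate_trigger_gain(spec, method, proteome, probe)
print(f"labeled peptides identified with trigger:    "
      f"{gain['ids_with_trigger']}")
print(f"labeled peptides identified without trigger: "
      f"{gain['ids_without']}")
print(f"relative identification gain:                "
      f"{gain['relative_gain']:.1%}")

# The gain is positive whenever stepped scans add fragment coverage that
# base-energy scans lack; with well-fragmenting peptides it saturates to ~0.
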