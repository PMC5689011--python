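"""Generator/analyzer closure of the acceptor-normalization E_FRET pipeline.

Synthesizes donor- and acceptor-excited emission spectra across the whole
efficiency range, recovers E_FRET by spectral deconvolution, and tabulates
the noiseless error plus the bias under 1% peak noise (20 seeds per level).
"""

from pathlib import Path

import numpy as np
import pandas as pd

import kturnfold as kf

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    rows = []
    for e_true in np.round(np.arange(0.0, 1.01, 0.1), 1):
        clean = kf.efret_from_spectra(kf.gen_spectra(float(e_true))).efret
        noisy = [
            kf.efret_from_spectra(
                kf.gen_spectra(float(e_true), noise=0.01, seed=s)
            ).efret
            for s in range(20)
        ]
        rows.append(
            {
                "e_true": e_true,
                "e_noiseless": round(clean, 6),
                "noiseless_error": round(clean - e_true, 9),
                "e_noisy_mean": round(float(np.mean(noisy)), 6),
                "noisy_bias": round(float(np.mean(noisy)) - e_true, 6),
                "noisy_sd": round(float(np.std(noisy, ddof=1)), 6),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "spectra_roundtrip.tsv", sep="\t", index=False)
    print(f"round trip over {len(table)} efficiency levels:")
    print(f"  max |noiseless error| = {table['noiseless_error'].abs().max():.2e}")
    print(f"  max |bias| at 1% noise = {table['noisy_bias'].abs().max():.4f}")


if __name__ == "__main__":
    main()
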