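"""Sweep the mixing weight of the combined ranker.

Uses a collection where the similarity channel is weak and the frequency
channel strong, so neither pure system wins alone: the sweep shows the
interior optimum that motivates linear score fusion.  lambda = 0 is the
pure frequency system, lambda = 1 the pure similarity system.
"""

import figrank as fr

cfg = fr.SynthConfig(n_articles=60, sim_signal=0.3, freq_signal=0.7,
                     noise=0.3, seed=3)
articles = fr.generate_articles(cfg)
idf = fr.collection_idf(articles)

table = fr.sweep_lambda(articles, idf)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

best = table.loc[table["mwer_rk"].idxmin()]
print()
print(f"best MWER-RK {best['mwer_rk']:.4f} at lambda={best['lambda']:.1f} "
      f"(endpoints: {table['mwer_rk'].iloc[0]:.4f} at 0.0, "
      f"{table['mwer_rk'].iloc[-1]:.4f} at 1.0)")
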