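"""Mine the packaged treatment-mean tables: correlation, clustering, PCA, CCA.

Uses the bundled fixtures: 15 PEG x proline treatment means for eleven
measured features (table1) and for the relative expression of six
monoterpene-pathway genes (table2).
"""

import pandas as pd

import qpcrmine as q
from qpcrmine.ctio import OIL_FEATURES, TraitTable
from qpcrmine.multivar import cca, pca_correlation, pearson_matrix, ward_cluster

table1 = q.load_fixture("table1")
table2 = q.load_fixture("table2")
oils = table1.subset(list(OIL_FEATURES))

cm = pearson_matrix(oils)
print("Strongest essential-oil correlations (|r|, p < 0.05):")
pairs = (
    cm.r.where(cm.significant)
    .stack()
    .loc[lambda s: s.index.get_level_values(0) < s.index.get_level_values(1)]
    .sort_values(key=abs, ascending=False)
)
for (a, b), r in pairs.head(3).items():
    print(f"  {a} ~ {b}: r = {r:.2f}")

cut = ward_cluster(oils, axis="features").cut(3)
print("\nWard/Euclidean clusters of the six oil profiles (k=3):")
for k in sorted(cut.unique()):
    print(f"  cluster {k}: {', '.join(cut.index[cut == k])}")

pca = pca_correlation(oils)
print(f"\nPCA of the oil correlation matrix: PC1 {pca.explained.iloc[0]:.1%}, "
      f"PC2 {pca.explained.iloc[1]:.1%} of variance")

joined = TraitTable(
    pd.concat([table2.values[["TPS27"]], table1.values[["1,8-cineole"]]], axis=1)
)
r = pearson_matrix(joined).r.loc["TPS27", "1,8-cineole"]
print(f"\nCross-set: TPS27 expression ~ 1,8-cineole content, r = {r:.2f}")

res = cca(table1, table2, ridge=1e-3)
print("Canonical correlations, expression set vs trait set (ridge 1e-3):")
print("  " + ", ".join(f"{c:.3f}" for c in res.correlations))
print()
print("High leading canonical correlations on 15 observations with 11+6")
print("variables reflect the small-n geometry and are read qualitatively.")
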