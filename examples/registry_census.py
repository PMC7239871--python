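"""Print the annotated-database census: structures per material class and
how many of each enter the three modeling endpoints."""

from nanotess.fixtures import registry_counts

table = registry_counts()
print(table.to_string())
print(f"\ntotal structures: {table['structures'].sum()}")
print(f"logP dataset: {table['logP'].sum()} structures")
print(f"zeta-potential dataset: {table['zeta_potential'].sum()} structures")
print(f"cellular-uptake dataset: {table['cellular_uptake'].sum()} structures")
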