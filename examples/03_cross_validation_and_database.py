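"""Cross-method validation and W-series database building.

Runs the gDNA and Sanger routes for three subjects drawn from one population
pool (so novel alleles recur across subjects), tabulates multi-evidence
support for every called sequence, and merges the validated novel alleles
into an updated reference database with deterministic W-series names
(nearest gene template + 'W' + four checksum digits).
"""

from ighvkit.compare import evidence_summary
from ighvkit.dbbuild import union_dbs
from ighvkit.simulate import SimParams, load_toy_db
from ighvkit.workflows import population_pool, run_gdna_route, run_sanger_route

db = load_toy_db()
pool = population_pool(db, seed=99, novel_fraction=0.25)
params = SimParams(
    n_alleles=60, novel_fraction=0.0, per_base_error=0.002, depth_log_mean=5.5,
    n_colonies=200, n_repertoire_reads=0,
)

call_sets = []
for i, sid in enumerate(("macA", "macB", "macC")):
    g = run_gdna_route(db, params, seed=200 + 10 * i, subject_id=sid, pool=pool)
    s = run_sanger_route(db, params, seed=200 + 10 * i, subject_id=sid, truth=g.truth)
    call_sets += [g.call_set, s.call_set]
    print(f"{sid}: {len(g.called)} gDNA calls, {len(s.called)} Sanger calls")

summ = evidence_summary(call_sets, [db])
print(f"\ndistinct sequences called : {summ.n_total}")
print(f"novel (absent from db)    : {summ.n_novel}")
print(f"  validated by >=2 methods           : {summ.n_novel_ge2_methods} "
      f"({summ.pct_novel_ge2_methods}%)")
print(f"  found in >=2 subjects              : {summ.n_novel_ge2_subjects}")
for method, row in summ.per_method_validation.items():
    print(f"  {method:<11} validation by other methods/dbs: "
          f"{row['pct_validated_by_methods_or_dbs']}%")

updated, ledger = union_dbs([db], [(str(s), None) for s in sorted(summ.table.novel_seqs())],
                            name="updated")
print(f"\nupdated database          : {len(updated)} alleles "
      f"(base {len(db)} + {len(ledger.assigned)} W-series)")
some = sorted(ledger.assigned.values(), key=lambda n: n.render())[:3]
print("example W-series names    :", ", ".join(n.render() for n in some))
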