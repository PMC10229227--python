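# Framework census fixture: a synthetic comparative framework with the same
# unit structure as the published early-vertebrate study (111 units, 71
# binary characters): four extant taxa expanded into semaphoronts and
# decay-stage semataphonts, plus synthetic fossil groups of matching sizes.
n_taxa: 4
n_chars: 71
n_decay_stages: 6
fraction_shared_resistant: 0.3
fraction_apomorphic: 0.3
retention_rule: resistant_last
seed: 0
taxa:
  # adult only; decay stages 1-6 of the adult -> 7 units
  - name: hagfish
    n_onto_stages: 1
    decayed_stages: [0]
  # ammocoete, metamorphic stages 1-7, adult; decay series of adult and
  # ammocoete -> 9 + 12 = 21 units
  - name: lamprey
    n_onto_stages: 9
    decayed_stages: [8, 0]
  # embryo and pre-hatchling, both decayed -> 2 + 12 = 14 units
  - name: shark
    n_onto_stages: 2
    decayed_stages: [0, 1]
  # adult only, decayed -> 7 units
  - name: branchiostoma
    n_onto_stages: 1
    decayed_stages: [0]
fossils:
  - {name: Myxinikela_synth, count: 1, source_taxon: hagfish, obscure_fraction: 0.3}
  - {name: Tethymyxine_synth, count: 1, source_taxon: hagfish, decay_stage: 1, obscure_fraction: 0.2}
  - {name: Mayomyzon_synth, count: 22, source_taxon: lamprey, obscure_fraction: 0.3}
  - {name: Priscomyzon_synth, count: 7, source_taxon: lamprey, obscure_fraction: 0.3}
  - {name: Mesomyzon_synth, count: 2, source_taxon: lamprey, obscure_fraction: 0.3}
  - {name: euphaneropoid_synth, count: 24, obscure_fraction: 0.4}
  - {name: Palaeospondylus_synth, count: 5, source_taxon: shark, obscure_fraction: 0.5,
     unit_class: fossil_version}
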