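# Noscapine: hydrogen-suppressed molecular graph (reconstructed-from-published-partition)
v1 v17
v17 v24
v2 v7
v7 v15
v3 v8
v8 v11
v4 v25
v25 v16
v25 v19
v5 v30
v30 v10
v30 v27
v30 v28
v6 v21
v6 v28
v21 v18
v21 v20
v28 v22
v15 v20
v11 v23
v9 v18
v9 v12
v12 v23
v10 v26
v26 v13
v26 v24
v23 v29
v13 v14
v14 v19
v19 v16
v20 v24
v22 v27
v22 v29
v27 v29
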