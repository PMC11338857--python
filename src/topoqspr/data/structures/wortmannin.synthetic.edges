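# Wortmannin: hydrogen-suppressed molecular graph (reconstructed-from-published-partition)
v1 v19
v19 v11
v19 v21
v2 v30
v30 v3
v30 v14
v30 v31
v4 v23
v23 v25
v23 v29
v5 v20
v20 v6
v20 v22
v7 v15
v15 v13
v8 v22
v22 v12
v9 v13
v9 v28
v28 v16
v28 v24
v10 v24
v10 v31
v24 v14
v31 v26
v31 v29
v11 v18
v18 v26
v18 v27
v12 v27
v27 v21
v16 v17
v17 v25
v25 v26
v21 v29
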