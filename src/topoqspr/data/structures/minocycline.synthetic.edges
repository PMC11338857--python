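# Minocycline: hydrogen-suppressed molecular graph (reconstructed-from-published-partition)
v1 v17
v17 v10
v17 v33
v2 v27
v27 v15
v27 v29
v3 v19
v19 v32
v19 v23
v4 v24
v24 v20
v24 v34
v5 v25
v25 v28
v25 v26
v6 v16
v16 v26
v16 v18
v7 v21
v21 v13
v21 v20
v8 v26
v9 v15
v15 v23
v11 v30
v30 v12
v30 v14
v30 v35
v23 v22
v18 v29
v18 v31
v33 v29
v29 v31
v31 v28
v31 v34
v32 v35
v20 v22
v22 v28
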