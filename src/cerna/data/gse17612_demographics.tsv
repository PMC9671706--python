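Sample	Source name	Age	Gender	Ph	Post-mortem delay (h)
GSM439778	Brain BA10 post-mortem schizophrenic	74	Male	6	4.5
GSM439779	Brain BA10 post-mortem control	72	Male	6.8	12
GSM439780	Brain BA10 post-mortem control	89	Female	6.5	5
GSM439781	Brain BA10 post-mortem schizophrenic	85	Female	5.9	3.5
GSM439782	Brain BA10 post-mortem control	61	Male	6.2	16.5
GSM439783	Brain BA10 post-mortem control	54	Female	6.5	4
GSM439784	Brain BA10 post-mortem schizophrenic	41	Male	6.3	8
GSM439785	Brain BA10 post-mortem schizophrenic	71	Male	6	6.5
GSM439786	Brain BA10 post-mortem schizophrenic	77	Male	6.1	3
GSM439787	Brain BA10 post-mortem control	90	Female	5.7	12.5
GSM439788	Brain BA10 post-mortem control	91	NA	6.3	4.5
GSM439789	Brain BA10 post-mortem control	54	Male	6.6	12
GSM439790	Brain BA10 post-mortem schizophrenic	65	Female	6.1	3
GSM439791	Brain BA10 post-mortem schizophrenic	75	Male	6.3	9
GSM439792	Brain BA10 post-mortem control	78	Female	6.7	8
GSM439793	Brain BA10 post-mortem control	90	Male	6.2	6.75
GSM439794	Brain BA10 post-mortem schizophrenic	56	Male	6.4	16.5
GSM439795	Brain BA10 post-mortem schizophrenic	81	Female	NA	22
GSM439796	Brain BA10 post-mortem schizophrenic	82	Male	6	11
GSM439797	Brain BA10 post-mortem control	91	Male	6.3	9.5
GSM439798	Brain BA10 post-mortem schizophrenic	82	Male	6.4	11
GSM439799	Brain BA10 post-mortem control	58	Male	6.5	15
GSM439800	Brain BA10 post-mortem schizophrenic	28	Female	6.3	11
GSM439801	Brain BA10 post-mortem schizophrenic	87	Male	6	3.5
GSM439802	Brain BA10 post-mortem control	87	Female	6.5	14.5
GSM439803	Brain BA10 post-mortem schizophrenic	72	Male	6.6	20
GSM439804	Brain BA10 post-mortem control	25	Male	6.9	17
GSM439805	Brain BA10 post-mortem schizophrenic	82	Female	5.9	8.5
GSM439806	Brain BA10 post-mortem schizophrenic	79	Male	6.1	4.5
GSM439807	Brain BA10 post-mortem schizophrenic	88	Female	5.7	7
GSM439808	Brain BA10 post-mortem control	94	Female	6.3	9.5
GSM439809	Brain BA10 post-mortem schizophrenic	63	Male	6.5	30
GSM439810	Brain BA10 post-mortem control	46	Female	6.6	4
GSM439811	Brain BA10 post-mortem schizophrenic	75	Female	6	3
GSM439812	Brain BA10 post-mortem control	68	Female	6.4	6
GSM439813	Brain BA10 post-mortem schizophrenic	83	Male	6.1	11.5
GSM439814	Brain BA10 post-mortem control	60	Male	6.9	16
GSM439815	Brain BA10 post-mortem schizophrenic	79	Male	6.3	4.5
GSM439816	Brain BA10 post-mortem control	38	Male	6.9	6
GSM439817	Brain BA10 post-mortem schizophrenic	79	Male	6.2	4
GSM439818	Brain BA10 post-mortem control	71	Female	6.3	13
GSM439819	Brain BA10 post-mortem control	91	Male	6.3	13
GSM439820	Brain BA10 post-mortem schizophrenic	97	Female	6.2	3.5
GSM439821	Brain BA10 post-mortem schizophrenic	82	Male	5.8	19.5
GSM439822	Brain BA10 post-mortem control	25	Male	6.6	12
GSM439823	Brain BA10 post-mortem schizophrenic	82	Male	6.2	5
GSM439824	Brain BA10 post-mortem schizophrenic	44	Male	6.3	4
GSM439825	Brain BA10 post-mortem control	88	Female	6.8	5
GSM439826	Brain BA10 post-mortem control	67	Female	6.7	6
GSM439827	Brain BA10 post-mortem schizophrenic	67	Female	6.1	3.5
GSM439828	Brain BA10 post-mortem schizophrenic	77	Male	6.2	3
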