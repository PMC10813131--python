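/root/pkg/testsoracles.py__init__.pytest_synth.pytest_preprocess.pytest_graph.pytest_pipeline_cli.pytest_stats.pytest_acceptance.pytest_connectivity.pyconftest.py      �   ����o�k�%D$�k?��         �   �����^�I�^T�k?��         �   ������ٲ�E�k?��         �   \����w����"�k?��         �   (����=$����ˁk?��         �   �����Y�/�W�k?��         �   �������E7�k?��         �   �����?���F�k?��         �   q���b�k��3�B�k?��         �   G����]A���Ӂk?��                                         �n7 aay!S�n7 aay!S��������� �   ��������
      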